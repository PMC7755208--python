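# rescaff

Toolkit for **topological rescaffolding** of discontinuous protein binding
epitopes: given a receptor-binding surface whose critical residues sit on two
disconnected backbone segments of a donor protein (the motivating case is
G-CSF site II — K16, E19, Q20, R22, K23, D27 on one helix face and D109, D112
on another), find simpler host scaffolds that can hold the same residues in
the same 3D arrangement, plan the graft, score the resulting decoys, measure
how tightly structural ensembles of the designs cluster, and quantify
receptor binding from SPR sensograms.

## What it computes

**Two-segment geometric search.** The epitope is disembodied as two backbone
segments with CA positions *q* and dihedrals (φ_q, ψ_q). A subject chain is
scanned over all windows (l, g): segment 1 at l…l+k₁, segment 2 at
l+k₁+g…l+k₁+g+k₂. Three objectives are applied as sequential filter tiers:

- f₁ = ‖(s_l − s_{l+k₁}) × (s_{l+k₁+g} − s_{l+k₁+g+k₂}) − (q₁ − q_{1+k₁}) ×
  (q_{2+k₁} − q_{2+k₁+k₂})‖ — mutual orientation of the segment axes
  (evaluated after canonicalising the window frame, see `docs/methods.md`);
- f₂ = (|q_{1+k₁} − q_{2+k₁}| − |s_{l+k₁} − s_{l+k₁+g}|)² + (|q₁ −
  q_{2+k₁+k₂}| − |s_l − s_{l+k₁+g+k₂}|)² — cross-segment termini distances;
- f₃ = √[(Σᵢ(φ_q,i ⊖ φ_s,i)² + Σᵢ(ψ_q,i ⊖ ψ_s,i)²)/2n] — RMS periodic
  dihedral deviation.

Survivors are Kabsch-superposed (backbone N/CA/C of both segments jointly)
onto the query and re-ranked by RMSD; hot spots are then mapped onto the best
window to produce a graft plan.

**Decoy scores.** Packing quality as the ruggedness of the radial
distribution function, ∫₀⁴ |dg/dr| dr (discrete total variation over
0–4 Å), and relative contact order RCO = (1/LN) Σ |i−j| over heavy-atom
contacts.

**Ensemble metrics.** RMSD of each model to the iteratively superposed
average structure, locally aligned epitope RMSD against a reference, and
cross-replica mean pairwise RMSD (conformational homogeneity of simulation
repeats).

**SPR 1:1 kinetics (linearization method).** Per analyte concentration C the
association phase is fit as Γ(t) = c + a·e^(−bt) minimising
χ² = Σ(Γ_fit − Γ_obs)²/(n − p) (n = 900, p = 3) with bounded Nelder–Mead
(tol 1e-12, ≤10⁶ iterations; a ∈ (−700, 0), b ∈ (10⁻⁴, 10⁻¹), c ∈ (0, 700)).
Then k_obs = k_a·C + k_d by ordinary least squares gives k_a (slope), k_d
(intercept) and K_d = k_d/k_a, with leave-one-concentration-out standard
deviations.

## Worked example

Plant a rigid copy of a two-segment epitope inside a decoy chain, search for
it, and fit a simulated SPR series:

```
$ rescaff fixtures --kind planted_motif --seed 7 --outdir fx
$ rescaff search --query fx/donor.pdb --query-chain A \
    --seg1 4-15 --seg2 22-25 --hotspots A4,A22 \
    --subjects fx/planted_subject.pdb --top-m 50 --out hits.tsv
$ head -2 hits.tsv
structure  chain  l   g  swapped  f1      f2        f3      rmsd      mapping
planted_subject A  18  7  False   0.0063  5.5e-07   0.0543  0.00073   A4>A19;...
```

The planted window (donor offset 3 shifted by the 15-residue decoy flank,
so l = 18, gap offset g = 7) is recovered at rank 1 with RMSD at PDB
coordinate precision (7×10⁻⁴ Å).

```
$ rescaff spr-sim --ka 2.9e5 --kd 5.9e-3 --rmax 100 \
    --conc 2e-9 --conc 4e-9 --conc 8e-9 --conc 1.6e-8 --conc 3.2e-8 \
    --outdir spr
$ rescaff spr-fit --series spr/series.json --out kinetics.tsv
Kd = 2.034e-08 M -> kinetics.tsv
```

The fitted table reports k_a = 2.90×10⁵ M⁻¹s⁻¹, k_d = 5.90×10⁻³ s⁻¹,
K_d = 2.03×10⁻⁸ M with jackknife SDs ~10⁻⁸/10⁻¹⁶ (noiseless input: the
generating rates are recovered exactly and the leave-one-out refits agree to
numerical precision).

Packing/topology scores of any model:

```
$ rescaff rdf --in fx/donor.pdb --bin 0.1 --rmax 10 --out rdf.tsv
ruggedness      270.703536
$ rescaff co --in fx/donor.pdb
relative_contact_order  0.096533
```

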