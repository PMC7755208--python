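# Methods

## Structure model and geometry

Structures are parsed with gemmi (PDB and mmCIF). Only ATOM records of
polypeptide chains are kept; heteroatoms, waters, hydrogens and alternate
locations other than 'A'/blank are dropped (selenomethionine is retained as
methionine-equivalent). Author residue numbering is preserved for reporting;
all internal indexing is 0-based positional. A residue is eligible for
geometric windows when N, CA and C are present; a missing carbonyl O is
tolerated everywhere. Consecutive CA–CA distances above 4.5 Å mark chain
breaks; scan windows never place a segment across a break, while the
intervening gap may span one.

Dihedrals follow the IUPAC sign convention, computed by the atan2 torsion
formula and wrapped into (−180°, 180°] with −180° mapped to +180°. The
periodic difference a ⊖ b uses the same wrap, so a 179° vs −179° comparison
contributes 2°, never 358°. Superposition is Kabsch via SVD with the proper
rotation enforced (det R = +1); the test suite cross-checks it against an
independent quaternion eigenvalue oracle.

## Two-segment search

The query holds two break-free backbone segments of k₁+1 and k₂+1 residues
(for the G-CSF site II case: residues 16–27 and 109–112, so k₁ = 11,
k₂ = 3) plus the hot-spot identities. A window in a subject chain is
parameterised by the start l and gap offset g: segment 1 occupies indices
l…l+k₁ and segment 2 occupies l+k₁+g…l+k₁+g+k₂. Under this indexing g = 1
means sequence-adjacent segments and g−1 residues lie between them;
enumeration is exhaustive over all (l, g) with g up to the chain length.
Queries are matched in both sequence orders by default ("both"), since a
host topology may present the two segments reversed.

**Frame canonicalisation for f₁.** The orientation objective compares cross
products of the segment axis vectors and is therefore not invariant to a
rigid motion of the subject as printed. Before evaluating it we superpose
the four segment-endpoint CAs of the window onto the query's four endpoints,
which preserves the formula while making scores frame-independent. The
verbatim laboratory-frame evaluation (`frame="fixed"`) and a
magnitude-comparison mode (`frame="magnitude"`, fully invariant without any
alignment) are provided; which frame the original search used is not
documented, so the choice is exposed rather than asserted.

**Tiers.** No published thresholds exist for the three filters, so the
default keeps the best M = 2000 windows per tier across the pooled subject
set; absolute thresholds on f₁/f₂/f₃ are supported as an alternative.
Survivors are superposed on backbone N/CA/C of both segments jointly
(the atom set behind published "local backbone RMSD" values is not stated;
N/CA/C is the default and the atom tuple is a parameter) and re-ranked
ascending by RMSD with deterministic lexicographic tie-break on
(rmsd, structure, chain, l, g).

**Grafting** maps each hot spot through the window alignment, records
from→to substitutions (no-ops where the scaffold already carries the target
identity), and emits the scaffold with grafted residues renamed plus the
mutated sequence. Side-chain construction and sequence optimisation are
downstream design work, out of scope here.

## Packing and topology scores

g(r) is the pairwise-distance histogram of the selected atoms (all heavy
atoms by default; side-chain-only and CA-only selections available, since
the atom set behind the published filter is unstated) normalised by shell
volume 4πr²Δr and by the ideal-pair density N(N−1)/2V with V the
bounding-sphere volume. Bin width defaults to 0.1 Å. Ruggedness is the
discrete total variation Σ|g(r_{i+1}) − g(r_i)| over bin centers in
[0, 4] Å — a grid-robust form of ∫₀⁴|dg/dr|dr. The toolkit reports the
score without asserting a ranking direction; the decoy-filtering
interpretation (smoother = better packed, ascending rank) is configurable.

Relative contact order counts heavy-atom pairs within 6 Å between residues
≥ 2 apart in sequence: RCO = (1/LN) Σ|i−j|, bounded by (L−1)/L.

## Ensemble metrics

The "average structure" of an ensemble is defined operationally as the
iteratively superposed coordinate mean: seed with model 1, superpose all
models on the current mean, re-average, iterate to a 1e-6 Å fixed point.
Per-model RMSD to that mean and its ensemble average quantify global
deviation; locally aligned epitope RMSD superposes only the mapped epitope
stretches of each model onto the reference before measuring. All metrics
accept residue-range masks (for unassigned/disordered termini) and default
to backbone N/CA/C. Replica homogeneity is the mean pairwise superposed
RMSD across frames of different replicas, subsampled at a fixed seed (1729)
above 10,000 pairs.

## Loop enumeration

Loop candidates cover all sequence combinations of the 9-residue design
alphabet G, D, P, S, L, N, T, E, K at lengths 3 (9³ = 729) or 4 (9⁴ = 6561),
in stable lexicographic order. Conformational-stability ranking of loop
candidates is produced externally (MD); scores re-enter through a TSV hook
and rank ascending with lexicographic tie-break. Single-chain constructs are
assembled as A + loop + B with the junction indices recorded in the FASTA
header.

## SPR kinetics

The simulator integrates the 1:1 Langmuir model: association
R(t) = R_eq(1 − e^(−k_obs t)) with k_obs = k_a·C + k_d and
R_eq = R_max·C/(C + K_d), dissociation R(t_end)·e^(−k_d(t−t_end)); optional
Gaussian noise with a caller-supplied seed; C = 0 gives the blank used in
double-referencing (sample − reference − blank, elementwise on aligned
grids). Default sampling is 5 Hz over a 180 s association phase (900
points) followed by 360 s of dissociation.

Fitting follows the linearization method exactly: per concentration,
Γ(t) = c + a·e^(−bt) minimises χ² = Σ(Γ_fit − Γ_obs)²/(n − p) with p = 3,
using Nelder–Mead at tolerance 1e-12 and at most 10⁶ iterations within
bounds a ∈ (−7×10², 0), b ∈ (10⁻⁴, 10⁻¹) s⁻¹, c ∈ (0, 7×10²) RU. The
published procedure states the bounds but not the start point or the
bounding mechanism; we start from a₀ = −max Γ, b₀ = √(10⁻⁴·10⁻¹) ≈
3.16×10⁻³ s⁻¹ (geometric mean of the rate bounds), c₀ = max Γ, and use
scipy's bounded Nelder–Mead (clipped reflections). Fits ending on a bound
are flagged, not silently accepted; k_obs values outside the b bounds are
flagged rather than clipped. The k_obs values are regressed on C by OLS
(k_a = slope, k_d = intercept; a negative intercept is reported with a
warning, a known behaviour of the linearization approach), K_d = k_d/k_a
holds exactly in every estimate, and dispersion comes from N = 5
leave-one-concentration-out refits, s = √(Σ(xᵢ−x̄)²/(N−1)), including the
K_d values themselves. The series-level χ² is the mean per-fit χ².

## Synthetic data

Fixtures are built from internal coordinates (NeRF chain extension with
canonical bond lengths N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, standard
angles, ω = 180°), so ideal helices (φ, ψ = −57°, −47°) and strands
(−120°, 120°) invert exactly under dihedral measurement. The planted-motif
subject embeds a rigidly moved copy of a two-helix donor between
independently built coil flanks displaced far from the plant; the junctions
are genuine chain breaks, exercising the scanner's break handling.
Pseudo-NMR ensembles add per-model Gaussian coordinate noise and random
rigid motions. Sensogram series default to the multi-cycle design of the
binding assays: five 2-fold increasing concentrations, Rmax 100 RU,
noiseless unless asked otherwise.

What the synthetic fixtures do not emulate: real side-chain packing and
sequence diversity (fixtures are poly-Ala backbones), crystallographic
disorder, missing residues beyond simple breaks, correlated NMR restraint
noise, and instrument artifacts in sensograms (drift, bulk shifts,
mass-transport limitation). Passing tests therefore demonstrate
correctness of the geometry, search, scoring and fitting machinery — not
that any particular real scaffold will host a given epitope.

## Problem sizes and numerical choices

The test suite runs entirely on synthetic fixtures: donor chains of ~30
residues, planted subjects of ~60, ensembles of 3–6 models, SPR series of
5 × 900-point curves, and a 30-seed noise-recovery study; the full suite
completes in seconds. The two reproduction tests that need deposited PDB
structures (the scaffold-search RMSDs and the ensemble deviations) locate
the files under `data/pdb/` and fail with a clear message when the
depositions are not present, since they are not redistributable as
fixtures. Degenerate inputs are rejected explicitly: collinear dihedral
quadruples, <3-point superpositions, zero-length segment axes, windows with
no comparable dihedral positions, <2-atom RDF selections, contact-free
chains, <3-concentration jackknives.
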