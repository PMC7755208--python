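"""Deterministic synthetic fixtures.

Builds idealised polypeptide backbones from internal coordinates (NeRF
chain extension with canonical bond lengths/angles), plants rigid copies
of an epitope query inside decoy chains, perturbs structures into
pseudo-NMR ensembles and writes synthetic SPR sensogram series.  All
generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math

import numpy as np

from .structio import AA1TO3, Chain, Residue, Structure

# canonical backbone internal coordinates (Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 120.0)


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position the next atom from three predecessors and internals."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(angle),
                  bond * math.sin(angle) * math.cos(torsion),
                  bond * math.sin(angle) * math.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi: list[tuple[float, float]],
                   sequence: str | None = None,
                   chain_id: str = "A",
                   structure_id: str = "synthetic") -> Structure:
    """Build an N/CA/C backbone chain realising the given (φ, ψ) profile.

    ``phi_psi[i]`` supplies the torsions of residue i; φ of the first and
    ψ of the last residue are unused (undefined at termini).  Residues
    default to alanine.
    """
    n_res = len(phi_psi)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    seq = (sequence or "A" * n_res).upper()
    if len(seq) != n_res:
        raise ValueError("sequence length must match phi_psi length")

    # seed the first residue explicitly
    coords = {}
    coords[(0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(0, "CA")] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    coords[(0, "C")] = coords[(0, "CA")] + BOND_CA_C * np.array(
        [-math.cos(ang), math.sin(ang), 0.0])

    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        coords[(i, "N")] = _place_atom(coords[(i - 1, "N")], coords[(i - 1, "CA")],
                                       coords[(i - 1, "C")], BOND_C_N,
                                       ANGLE_CA_C_N, psi_prev)
        coords[(i, "CA")] = _place_atom(coords[(i - 1, "CA")], coords[(i - 1, "C")],
                                        coords[(i, "N")], BOND_N_CA,
                                        ANGLE_C_N_CA, OMEGA)
        phi_i = phi_psi[i][0]
        coords[(i, "C")] = _place_atom(coords[(i - 1, "C")], coords[(i, "N")],
                                       coords[(i, "CA")], BOND_CA_C,
                                       ANGLE_N_CA_C, phi_i)

    chain = Chain(id=chain_id)
    for i in range(n_res):
        res = Residue(name=AA1TO3.get(seq[i], "ALA"), resseq=i + 1,
                      atoms={a: coords[(i, a)] for a in ("N", "CA", "C")})
        chain.residues.append(res)
    return Structure(id=structure_id, chains=[chain], source_format="PDB")


def ideal_helix(n_res: int, **kw) -> Structure:
    """Ideal α-helix at (φ, ψ) = (−57, −47)."""
    return build_backbone([HELIX_PHI_PSI] * n_res, **kw)


def ideal_strand(n_res: int, **kw) -> Structure:
    """Ideal β-strand at (φ, ψ) = (−120, 120)."""
    return build_backbone([STRAND_PHI_PSI] * n_res, **kw)


def random_coil(n_res: int, seed: int, chain_id: str = "A",
                structure_id: str = "coil") -> Structure:
    """Backbone with φ/ψ drawn uniformly from allowed-ish ranges."""
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-150.0, -60.0, n_res)
    psi = rng.uniform(-60.0, 160.0, n_res)
    return build_backbone(list(zip(phi, psi)), chain_id=chain_id,
                          structure_id=structure_id)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_structure(structure: Structure, rotation: np.ndarray,
                        translation: np.ndarray,
                        new_id: str | None = None) -> Structure:
    """Apply a rigid motion to every atom; returns a deep copy."""
    out = Structure(id=new_id or structure.id, chains=[],
                    source_format=structure.source_format)
    for chain in structure.chains:
        nc = Chain(id=chain.id)
        for res in chain.residues:
            nr = Residue(name=res.name, resseq=res.resseq, icode=res.icode,
                         atoms={a: rotation @ xyz + translation
                                for a, xyz in res.atoms.items()})
            nc.residues.append(nr)
        out.chains.append(nc)
    return out


def two_segment_donor(k1: int = 11, k2: int = 3, gap: int = 6,
                      flank: int = 3, seed: int = 0,
                      structure_id: str = "donor") -> Structure:
    """A donor-like single chain: helix segment, coil gap, helix segment.

    The two helical stretches play the role of the discontinuous epitope
    segments (lengths k1+1 and k2+1 residues) separated by ``gap`` coil
    residues, with ``flank`` coil residues on both ends.  The native
    window therefore starts at index ``flank``.
    """
    rng = np.random.default_rng(seed)
    profile: list[tuple[float, float]] = []
    for _ in range(flank):
        profile.append((rng.uniform(-150, -60), rng.uniform(-60, 160)))
    profile += [HELIX_PHI_PSI] * (k1 + 1)
    for _ in range(gap):
        profile.append((rng.uniform(-150, -60), rng.uniform(-60, 160)))
    profile += [HELIX_PHI_PSI] * (k2 + 1)
    for _ in range(flank):
        profile.append((rng.uniform(-150, -60), rng.uniform(-60, 160)))
    return build_backbone(profile, structure_id=structure_id)


def planted_motif_subject(donor: Structure, chain_id: str = "A",
                          n_flank: int = 15, seed: int = 42,
                          structure_id: str = "planted") -> tuple[Structure, int]:
    """Embed a rigidly moved copy of a donor chain between random coils.

    Returns the subject structure and the 0-based offset at which the
    donor chain's residues start in the subject chain, so any window at
    donor index ``l`` appears at ``offset + l`` in the subject.  The
    junctions are genuine chain breaks (flanks are built independently),
    which exercises the scanner's break handling.
    """
    rng = np.random.default_rng(seed)
    rot = random_rotation(rng)
    trans = rng.uniform(-50, 50, 3)
    moved = transform_structure(donor, rot, trans)
    core = moved[chain_id]

    pre = random_coil(n_flank, seed=seed + 1)["A"]
    post = random_coil(n_flank, seed=seed + 2)["A"]
    # shift flanks far away so they cannot shadow the plant
    for res in pre.residues:
        for a in res.atoms:
            res.atoms[a] = res.atoms[a] + np.array([200.0, 0.0, 0.0])
    for res in post.residues:
        for a in res.atoms:
            res.atoms[a] = res.atoms[a] + np.array([-200.0, 0.0, 0.0])

    chain = Chain(id="A")
    for src in (pre, core, post):
        for res in src.residues:
            chain.residues.append(
                Residue(name=res.name, resseq=len(chain.residues) + 1,
                        atoms=dict(res.atoms)))
    return Structure(id=structure_id, chains=[chain]), n_flank


def noisy_ensemble(base: Structure, n_models: int, noise_sd: float,
                   seed: int, rigid: bool = True) -> list[Structure]:
    """Pseudo-NMR ensemble: per-model Gaussian coordinate noise plus an
    optional random rigid motion (models are deposited in arbitrary frames)."""
    rng = np.random.default_rng(seed)
    models = []
    for m in range(n_models):
        st = Structure(id=f"{base.id}_m{m + 1}", chains=[])
        rot = random_rotation(rng) if rigid else np.eye(3)
        trans = rng.uniform(-20, 20, 3) if rigid else np.zeros(3)
        for chain in base.chains:
            nc = Chain(id=chain.id)
            for res in chain.residues:
                atoms = {a: rot @ (xyz + rng.normal(0.0, noise_sd, 3)) + trans
                         for a, xyz in res.atoms.items()}
                nc.residues.append(Residue(name=res.name, resseq=res.resseq,
                                           icode=res.icode, atoms=atoms))
            st.chains.append(nc)
        models.append(st)
    return models
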