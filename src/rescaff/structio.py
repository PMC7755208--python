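"""Structure I/O and geometry primitives.

Reads protein structures from PDB or mmCIF files into a light-weight
in-memory model (:class:`Structure` → :class:`Chain` → :class:`Residue`)
and provides the geometric operations every other module builds on:
backbone dihedral angles, periodic angular arithmetic, Kabsch
least-squares superposition and backbone RMSD.

Parsing policy: only ATOM records of polypeptide chains are kept;
heteroatoms, waters, hydrogens and alternate locations other than
'A'/blank are dropped.  Author residue numbering is preserved for
reporting while all internal indexing is 0-based positional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "Chain",
    "Structure",
    "BackboneSegment",
    "Superposition",
    "StructureParseError",
    "read_structure",
    "read_models",
    "write_structure",
    "dihedral",
    "angular_diff",
    "superpose",
    "backbone_dihedrals",
    "rmsd",
    "AA3TO1",
    "AA1TO3",
]

#: Sentinel for undefined dihedral angles (chain termini, missing atoms).
UNDEFINED_ANGLE = math.nan

#: Consecutive CA–CA distances above this mark a chain break (Å).
BREAK_THRESHOLD = 4.5

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
AA1TO3 = {v: k for k, v in AA3TO1.items() if k not in ("MSE",)}


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed or holds no polypeptide."""


@dataclass
class Residue:
    """One amino-acid residue: name, author numbering and atom coordinates."""

    name: str
    resseq: int
    icode: str = ""
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def one_letter(self) -> str:
        return AA3TO1.get(self.name, "X")

    @property
    def backbone_complete(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))

    @property
    def label(self) -> str:
        return f"{self.one_letter}{self.resseq}{self.icode.strip()}"

    def __getitem__(self, atom: str) -> np.ndarray:
        return self.atoms[atom]


@dataclass
class Chain:
    """An ordered polypeptide chain."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(L, 3) CA coordinates; rows of NaN where CA is missing."""
        out = np.full((len(self.residues), 3), np.nan)
        for i, r in enumerate(self.residues):
            if "CA" in r.atoms:
                out[i] = r.atoms["CA"]
        return out

    def break_mask(self, threshold: float = BREAK_THRESHOLD) -> np.ndarray:
        """Boolean array of length L-1; True where CA(i)→CA(i+1) is a break."""
        ca = self.ca_coords()
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        return ~(d <= threshold)  # NaN distances count as breaks

    def index_of(self, resseq: int, icode: str = "") -> int:
        for i, r in enumerate(self.residues):
            if r.resseq == resseq and r.icode.strip() == icode.strip():
                return i
        raise KeyError(f"residue {resseq}{icode} not in chain {self.id}")


@dataclass
class Structure:
    """A parsed structure: one model's polypeptide chains."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "PDB"

    def __getitem__(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in structure {self.id}")

    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]


@dataclass
class BackboneSegment:
    """A contiguous, break-free stretch of backbone-complete residues.

    phi/psi carry NaN sentinels where the flanking atom needed for the
    dihedral lies outside the segment's parent context.
    """

    residues: list[Residue]
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValueError("a backbone segment needs at least 2 residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca(self) -> np.ndarray:
        return np.asarray([r.atoms["CA"] for r in self.residues])

    def backbone_coords(self, atoms: Sequence[str] = ("N", "CA", "C")) -> np.ndarray:
        return np.asarray([r.atoms[a] for r in self.residues for a in atoms])

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class Superposition:
    """Optimal rigid-body map x ↦ R·x + t with its residual RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# File reading


def _convert_model(model: gemmi.Model, struct_id: str, fmt: str) -> Structure:
    out = Structure(id=struct_id, source_format=fmt)
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            if gres.het_flag != "A":  # HETATM (waters, ligands, MSE handled below)
                if gres.name != "MSE":
                    continue
            res = Residue(name=gres.name, resseq=gres.seqid.num,
                          icode=(gres.seqid.icode or "").strip())
            for atom in gres:
                if atom.element.is_hydrogen:
                    continue
                if atom.altloc not in ("", "A", "\0"):
                    continue
                res.atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
            if res.atoms:
                chain.residues.append(res)
        # polypeptide heuristic: a chain must carry CA atoms
        if chain.residues and any("CA" in r.atoms for r in chain.residues):
            out.chains.append(chain)
    return out


def _detect_format(path: Path) -> str:
    suffixes = "".join(path.suffixes).lower()
    return "mmCIF" if ".cif" in suffixes else "PDB"


def read_models(path: str | Path, fmt: str | None = None) -> list[Structure]:
    """Read every MODEL of a structure file as a separate :class:`Structure`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _detect_format(path)
    try:
        if fmt.upper() in ("MMCIF", "CIF"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
            fmt = "mmCIF"
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
            fmt = "PDB"
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    struct_id = st.name or path.stem
    models = [_convert_model(m, struct_id, fmt) for m in st]
    models = [m for m in models if m.chains]
    if not models:
        raise StructureParseError(f"{path}: no polypeptide chains found")
    return models


def read_structure(path: str | Path, fmt: str | None = None,
                   model: int = 0) -> Structure:
    """Read one model (default: the first) from a PDB or mmCIF file."""
    return read_models(path, fmt=fmt)[model]


def write_structure(structure: Structure | Iterable[Structure],
                    path: str | Path) -> None:
    """Write one structure (or an iterable of models) as a PDB file."""
    models = [structure] if isinstance(structure, Structure) else list(structure)
    st = gemmi.Structure()
    st.name = models[0].id
    for i, mod in enumerate(models):
        gm = gemmi.Model(i + 1)
        for chain in mod.chains:
            gc = gemmi.Chain(chain.id)
            for res in chain.residues:
                gr = gemmi.Residue()
                gr.name = res.name
                gr.seqid = gemmi.SeqId(res.resseq, res.icode or " ")
                gr.het_flag = "A"
                for name, xyz in res.atoms.items():
                    ga = gemmi.Atom()
                    ga.name = name
                    ga.element = gemmi.Element(name[:1] if name[:1] != "1" else "H")
                    ga.pos = gemmi.Position(*map(float, xyz))
                    ga.occ = 1.0
                    gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Geometry primitives


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1–p2–p3–p4 in degrees, IUPAC sign, range (−180, 180].

    Invariant under global rigid motion.  Raises for degenerate
    (collinear-axis) configurations where the angle is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("undefined dihedral: degenerate/collinear points")
    x = float(np.dot(n1, n2))
    y = float(nb2 * np.dot(b1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:  # boundary convention: −180 maps to +180
        ang += 360.0
    return ang


def angular_diff(a, b):
    """Periodic difference a ⊖ b in degrees, wrapped into (−180, 180].

    Works elementwise on arrays; NaN inputs propagate.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    wrapped = -(np.mod(-d + 180.0, 360.0) - 180.0)  # maps -180 -> +180
    if np.ndim(wrapped) == 0:
        return float(wrapped)
    return wrapped


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two equally-shaped point sets (Å)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Kabsch least-squares superposition of ``mobile`` onto ``target``.

    Returns the proper rotation R and translation t minimising
    Σ‖R·x + t − y‖², together with the residual RMSD.
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"point-set shapes differ: {x.shape} vs {y.shape}")
    if x.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    moved = x @ rot.T + trans
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd(moved, y))


def backbone_dihedrals(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue φ and ψ for a chain, NaN where undefined.

    φ_i uses C(i−1)–N(i)–CA(i)–C(i); ψ_i uses N(i)–CA(i)–C(i)–N(i+1).
    Terminal residues and residues adjacent to chain breaks or missing
    backbone atoms receive the NaN sentinel.
    """
    n = len(chain)
    phi = np.full(n, UNDEFINED_ANGLE)
    psi = np.full(n, UNDEFINED_ANGLE)
    breaks = chain.break_mask() if n > 1 else np.array([], bool)
    for i, res in enumerate(chain.residues):
        if not res.backbone_complete:
            continue
        if i > 0 and not breaks[i - 1]:
            prev = chain.residues[i - 1]
            if "C" in prev.atoms:
                try:
                    phi[i] = dihedral(prev["C"], res["N"], res["CA"], res["C"])
                except ValueError:
                    pass
        if i < n - 1 and not breaks[i]:
            nxt = chain.residues[i + 1]
            if "N" in nxt.atoms:
                try:
                    psi[i] = dihedral(res["N"], res["CA"], res["C"], nxt["N"])
                except ValueError:
                    pass
    return phi, psi


def extract_segment(chain: Chain, start: int, stop: int,
                    phi: np.ndarray | None = None,
                    psi: np.ndarray | None = None) -> BackboneSegment:
    """Slice a :class:`BackboneSegment` out of a chain by 0-based indices.

    ``stop`` is inclusive.  Dihedrals are computed in the chain context
    (so the segment's first φ / last ψ are defined when neighbours exist)
    unless precomputed arrays are supplied.
    """
    if phi is None or psi is None:
        phi, psi = backbone_dihedrals(chain)
    residues = chain.residues[start:stop + 1]
    if any(not r.backbone_complete for r in residues):
        raise ValueError("segment contains backbone-incomplete residues")
    if np.any(chain.break_mask()[start:stop]):
        raise ValueError("segment spans a chain break")
    return BackboneSegment(residues=residues,
                           phi=np.array(phi[start:stop + 1]),
                           psi=np.array(psi[start:stop + 1]))
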