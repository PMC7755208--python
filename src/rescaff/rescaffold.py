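"""Two-segment discontinuous epitope search and graft planning.

The query is a pair of backbone segments disembodied from a donor
structure (for G-CSF site II: residues 16–27 and 109–112 plus the eight
hot-spot identities).  A subject chain is scanned over all windows
(l, g): segment 1 spans positions l…l+k1, a gap of g residues, and
segment 2 spans l+k1+g…l+k1+g+k2.  Three objective functions score each
window —

* f1, internal orientation: the norm of the difference between the
  cross products of the two segment axis vectors of subject and query;
* f2, termini distances: squared differences of the two cross-segment
  CA–CA distances;
* f3, dihedral profile: RMS periodic deviation of φ/ψ across the window

— applied as sequential filter tiers, after which survivors are
superposed (backbone N/CA/C of both segments jointly) onto the query and
re-ranked by RMSD.

The printed f1 is frame-dependent; by default the subject window is
first canonicalised by Kabsch-superposing its four segment-endpoint CAs
onto the query's, which makes the score rigid-motion invariant while
keeping the formula intact.  ``frame="fixed"`` evaluates it verbatim in
the laboratory frame; ``frame="magnitude"`` compares only the cross
product magnitudes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .structio import (BackboneSegment, Chain, Structure, angular_diff,
                       backbone_dihedrals, extract_segment, superpose)

__all__ = [
    "EpitopeQuery", "ScanWindow", "SearchHit", "GraftPlan", "TierConfig",
    "build_query", "score_orientation", "score_termini", "score_dihedrals",
    "scan_structure", "tiered_search", "graft_epitope", "parse_hotspot",
]


def parse_hotspot(spec: str) -> tuple[str, int]:
    """'K16' → ('K', 16)."""
    m = re.fullmatch(r"([A-Za-z])(-?\d+)", spec.strip())
    if not m:
        raise ValueError(f"malformed hotspot {spec!r}; expected e.g. 'K16'")
    return m.group(1).upper(), int(m.group(2))


@dataclass
class EpitopeQuery:
    """The disembodied epitope: two segments plus hot-spot identities.

    ``hotspots`` holds (segment index, residue offset within segment,
    1-letter target identity).
    """

    segment1: BackboneSegment
    segment2: BackboneSegment
    hotspots: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def k1(self) -> int:
        return len(self.segment1) - 1

    @property
    def k2(self) -> int:
        return len(self.segment2) - 1

    @property
    def q(self) -> np.ndarray:
        """Concatenated CA position vectors, segment 1 then segment 2."""
        return np.vstack([self.segment1.ca, self.segment2.ca])

    def swapped(self) -> "EpitopeQuery":
        """The same epitope with segment order exchanged (for scaffolds whose
        topology presents the segments in reverse sequence order)."""
        remapped = [(1 - s, o, aa) for s, o, aa in self.hotspots]
        return EpitopeQuery(segment1=self.segment2, segment2=self.segment1,
                            hotspots=remapped)

    def phi_psi(self) -> tuple[np.ndarray, np.ndarray]:
        phi = np.concatenate([self.segment1.phi, self.segment2.phi])
        psi = np.concatenate([self.segment1.psi, self.segment2.psi])
        return phi, psi


@dataclass
class ScanWindow:
    """One candidate (l, g) placement with its three tier scores."""

    l: int
    g: int
    f1: float
    f2: float
    f3: float
    swapped: bool = False  # True when matched against the order-swapped query


@dataclass
class SearchHit:
    structure_id: str
    chain_id: str
    window: ScanWindow
    rmsd: float
    mapping: list[tuple[str, str]]  # (query residue label, subject residue label)


@dataclass
class GraftPlan:
    scaffold_id: str
    substitutions: list[tuple[str, str, str]]  # (subject residue, from-aa, to-aa)
    epitope_rmsd: float

    @property
    def n_effective(self) -> int:
        return sum(1 for _, frm, to in self.substitutions if frm != to)


def build_query(donor: Structure, chain_id: str,
                seg1: tuple[int, int], seg2: tuple[int, int],
                hotspots: list[str] | None = None) -> EpitopeQuery:
    """Disembody an epitope query from a donor chain.

    ``seg1``/``seg2`` are inclusive author residue-number ranges.
    Hot spots are given as identity+number strings ('K16'); each is
    validated against the donor sequence and located within a segment.
    """
    chain = donor[chain_id]
    ranges = []
    for lo, hi in (seg1, seg2):
        i0, i1 = chain.index_of(lo), chain.index_of(hi)
        if i1 <= i0:
            raise ValueError(f"bad segment range {lo}-{hi}")
        ranges.append((i0, i1))
    phi, psi = backbone_dihedrals(chain)
    s1 = extract_segment(chain, *ranges[0], phi=phi, psi=psi)
    s2 = extract_segment(chain, *ranges[1], phi=phi, psi=psi)

    parsed: list[tuple[int, int, str]] = []
    for spec in hotspots or []:
        aa, num = parse_hotspot(spec)
        idx = chain.index_of(num)
        actual = chain.residues[idx].one_letter
        if actual != aa:
            raise ValueError(
                f"hotspot {spec}: donor has {actual}{num}, not {aa}{num}")
        for seg_i, (i0, i1) in enumerate(ranges):
            if i0 <= idx <= i1:
                parsed.append((seg_i, idx - i0, aa))
                break
        else:
            raise ValueError(f"hotspot {spec} lies outside both segments")
    return EpitopeQuery(segment1=s1, segment2=s2, hotspots=parsed)


# ---------------------------------------------------------------------------
# Objective functions


def _axis_cross(ca1: np.ndarray, ca2: np.ndarray) -> np.ndarray:
    """Cross product of the two segment axis vectors (start − end form)."""
    a = ca1[0] - ca1[-1]
    b = ca2[0] - ca2[-1]
    if np.linalg.norm(a) < 1e-9 or np.linalg.norm(b) < 1e-9:
        raise ValueError("degenerate zero-length segment axis")
    return np.cross(a, b)


def score_orientation(query: EpitopeQuery, seg1_ca: np.ndarray,
                      seg2_ca: np.ndarray, frame: str = "canonical") -> float:
    """f1: mismatch of the segments' mutual orientation (Å² scale)."""
    q1, q2 = query.segment1.ca, query.segment2.ca
    qc = _axis_cross(q1, q2)
    if frame == "magnitude":
        sc = _axis_cross(seg1_ca, seg2_ca)
        return float(abs(np.linalg.norm(sc) - np.linalg.norm(qc)))
    if frame == "canonical":
        s_ends = np.array([seg1_ca[0], seg1_ca[-1], seg2_ca[0], seg2_ca[-1]])
        q_ends = np.array([q1[0], q1[-1], q2[0], q2[-1]])
        sup = superpose(s_ends, q_ends)
        seg1_ca = sup.apply(seg1_ca)
        seg2_ca = sup.apply(seg2_ca)
    elif frame != "fixed":
        raise ValueError(f"unknown frame mode {frame!r}")
    sc = _axis_cross(seg1_ca, seg2_ca)
    return float(np.linalg.norm(sc - qc))


def score_termini(query: EpitopeQuery, seg1_ca: np.ndarray,
                  seg2_ca: np.ndarray) -> float:
    """f2: squared mismatch of the two cross-segment end-to-end distances (Å²)."""
    q1, q2 = query.segment1.ca, query.segment2.ca
    d_inner_q = np.linalg.norm(q1[-1] - q2[0])
    d_outer_q = np.linalg.norm(q1[0] - q2[-1])
    d_inner_s = np.linalg.norm(seg1_ca[-1] - seg2_ca[0])
    d_outer_s = np.linalg.norm(seg1_ca[0] - seg2_ca[-1])
    return float((d_inner_q - d_inner_s) ** 2 + (d_outer_q - d_outer_s) ** 2)


def score_dihedrals(query: EpitopeQuery, phi_s: np.ndarray,
                    psi_s: np.ndarray) -> float:
    """f3: RMS periodic φ/ψ deviation over comparable positions (degrees).

    Positions where either side carries the NaN sentinel are excluded
    pairwise; n counts residues with at least one comparable angle.
    """
    phi_q, psi_q = query.phi_psi()
    dphi = angular_diff(phi_q, phi_s)
    dpsi = angular_diff(psi_q, psi_s)
    ok_phi = ~np.isnan(dphi)
    ok_psi = ~np.isnan(dpsi)
    n = int(np.sum(ok_phi | ok_psi))
    if n == 0:
        raise ValueError("no comparable dihedral positions")
    total = float(np.sum(dphi[ok_phi] ** 2) + np.sum(dpsi[ok_psi] ** 2))
    return float(np.sqrt(total / (2.0 * n)))


# ---------------------------------------------------------------------------
# Scanning


def _scan_chain_one_order(chain: Chain, query: EpitopeQuery,
                          g_min: int, g_max: int, frame: str,
                          swapped: bool) -> list[ScanWindow]:
    k1, k2 = query.k1, query.k2
    L = len(chain)
    # a window spans k1 + g + k2 + 1 residues (indices l .. l+k1+g+k2)
    if L < k1 + k2 + g_min + 1:
        return []
    ca = chain.ca_coords()
    phi, psi = backbone_dihedrals(chain)
    breaks = chain.break_mask()
    # ok_run[i, k] would say span i..i+k break-free; use prefix sums instead
    bprefix = np.concatenate([[0], np.cumsum(breaks.astype(int))])

    def span_ok(i: int, j: int) -> bool:
        """True when residues i..j (inclusive) are break-free and CA-complete."""
        return (bprefix[j] - bprefix[i]) == 0 and not np.isnan(ca[i:j + 1]).any()

    out: list[ScanWindow] = []
    g_hi = min(g_max, L - k1 - k2 - 1)
    for g in range(g_min, g_hi + 1):
        for l in range(0, L - (k1 + k2 + g)):
            e1 = l + k1
            s2 = l + k1 + g
            e2 = s2 + k2
            if not (span_ok(l, e1) and span_ok(s2, e2)):
                continue
            seg1_ca = ca[l:e1 + 1]
            seg2_ca = ca[s2:e2 + 1]
            phi_s = np.concatenate([phi[l:e1 + 1], phi[s2:e2 + 1]])
            psi_s = np.concatenate([psi[l:e1 + 1], psi[s2:e2 + 1]])
            try:
                f1 = score_orientation(query, seg1_ca, seg2_ca, frame=frame)
            except ValueError:
                continue
            f2 = score_termini(query, seg1_ca, seg2_ca)
            f3 = score_dihedrals(query, phi_s, psi_s)
            out.append(ScanWindow(l=l, g=g, f1=f1, f2=f2, f3=f3,
                                  swapped=swapped))
    return out


def scan_structure(subject: Structure, query: EpitopeQuery,
                   g_min: int = 1, g_max: int | None = None,
                   order: str = "both",
                   frame: str = "canonical") -> dict[str, list[ScanWindow]]:
    """Exhaustively enumerate and score all (l, g) windows per chain.

    ``order``: 'forward' matches query segments in sequence order,
    'swapped' in reverse order, 'both' scans both.  Windows whose
    segments contain a chain break or missing CA are excluded; the gap
    region may span breaks.
    """
    if order not in ("forward", "swapped", "both"):
        raise ValueError(f"unknown order {order!r}")
    results: dict[str, list[ScanWindow]] = {}
    for chain in subject.chains:
        g_hi = g_max if g_max is not None else len(chain)
        windows: list[ScanWindow] = []
        if order in ("forward", "both"):
            windows += _scan_chain_one_order(chain, query, g_min, g_hi,
                                             frame, swapped=False)
        if order in ("swapped", "both"):
            windows += _scan_chain_one_order(chain, query.swapped(), g_min,
                                             g_hi, frame, swapped=True)
        results[chain.id] = windows
    return results


@dataclass
class TierConfig:
    """Sequential tier filters: keep top-M per tier, or absolute thresholds."""

    top_m: int = 2000
    f1_max: float | None = None
    f2_max: float | None = None
    f3_max: float | None = None


def _window_indices(window: ScanWindow, query: EpitopeQuery) -> tuple[range, range]:
    qq = query.swapped() if window.swapped else query
    k1, k2 = qq.k1, qq.k2
    l, g = window.l, window.g
    return range(l, l + k1 + 1), range(l + k1 + g, l + k1 + g + k2 + 1)


def _hit_from_window(structure: Structure, chain: Chain, window: ScanWindow,
                     query: EpitopeQuery,
                     atoms: tuple[str, ...] = ("N", "CA", "C")) -> SearchHit | None:
    qq = query.swapped() if window.swapped else query
    r1, r2 = _window_indices(window, query)
    subject_res = [chain.residues[i] for i in r1] + [chain.residues[i] for i in r2]
    if any(a not in r.atoms for r in subject_res for a in atoms):
        return None
    s_coords = np.asarray([r.atoms[a] for r in subject_res for a in atoms])
    q_res = qq.segment1.residues + qq.segment2.residues
    q_coords = np.asarray([r.atoms[a] for r in q_res for a in atoms])
    sup = superpose(s_coords, q_coords)
    mapping = [(qr.label, sr.label) for qr, sr in zip(q_res, subject_res)]
    return SearchHit(structure_id=structure.id, chain_id=chain.id,
                     window=window, rmsd=sup.rmsd, mapping=mapping)


def tiered_search(subjects: list[Structure], query: EpitopeQuery,
                  tiers: TierConfig | None = None,
                  g_min: int = 1, g_max: int | None = None,
                  order: str = "both", frame: str = "canonical",
                  atoms: tuple[str, ...] = ("N", "CA", "C"),
                  attrition: dict | None = None) -> list[SearchHit]:
    """Run the tiered search over a set of subject structures.

    All windows of all chains are pooled, filtered tier by tier on
    f1, f2, f3 (top-M per tier across the pool, or absolute thresholds
    when set), then superposed and re-ranked ascending by backbone RMSD.
    Ties break lexicographically on (rmsd, structure, chain, l, g).
    """
    if not subjects:
        raise ValueError("need at least one subject structure")
    tiers = tiers or TierConfig()
    pool: list[tuple[Structure, Chain, ScanWindow]] = []
    for st in subjects:
        per_chain = scan_structure(st, query, g_min=g_min, g_max=g_max,
                                   order=order, frame=frame)
        for chain in st.chains:
            for w in per_chain[chain.id]:
                pool.append((st, chain, w))

    counts = {"enumerated": len(pool)}
    for tier, thr in (("f1", tiers.f1_max), ("f2", tiers.f2_max),
                      ("f3", tiers.f3_max)):
        key = lambda item, tier=tier: getattr(item[2], tier)
        if thr is not None:
            pool = [item for item in pool if key(item) <= thr]
        else:
            pool = sorted(pool, key=key)[:tiers.top_m]
        counts[tier] = len(pool)
    if attrition is not None:
        attrition.update(counts)

    hits = []
    for st, chain, w in pool:
        hit = _hit_from_window(st, chain, w, query, atoms=atoms)
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (h.rmsd, h.structure_id, h.chain_id,
                             h.window.l, h.window.g))
    return hits


# ---------------------------------------------------------------------------
# Grafting


def graft_epitope(hit: SearchHit, query: EpitopeQuery,
                  scaffold: Structure) -> tuple[GraftPlan, Structure, str]:
    """Plan the hot-spot transplant onto a search hit.

    Returns the plan, a copy of the scaffold with grafted residues
    renamed to the hot-spot identities (backbone kept; side-chain
    construction is downstream design work), and the mutated sequence of
    the grafted chain.
    """
    qq = query.swapped() if hit.window.swapped else query
    chain = scaffold[hit.chain_id]
    r1, r2 = _window_indices(hit.window, query)
    seg_index = {0: list(r1), 1: list(r2)}

    substitutions: list[tuple[str, str, str]] = []
    targets: dict[int, str] = {}
    for seg_i, offset, aa in qq.hotspots:
        positions = seg_index[seg_i]
        if offset >= len(positions):
            raise ValueError(f"hotspot offset {offset} outside mapped window")
        pos = positions[offset]
        res = chain.residues[pos]
        substitutions.append((res.label, res.one_letter, aa))
        targets[pos] = aa

    from .structio import AA1TO3, Residue  # local to avoid cycle at import
    grafted = Structure(id=f"{scaffold.id}_graft", chains=[])
    for ch in scaffold.chains:
        nc = Chain(id=ch.id)
        for i, res in enumerate(ch.residues):
            name = res.name
            if ch.id == hit.chain_id and i in targets:
                name = AA1TO3[targets[i]]
            nc.residues.append(Residue(name=name, resseq=res.resseq,
                                       icode=res.icode, atoms=dict(res.atoms)))
        grafted.chains.append(nc)

    mutated_seq = grafted[hit.chain_id].sequence
    plan = GraftPlan(scaffold_id=scaffold.id, substitutions=substitutions,
                     epitope_rmsd=hit.rmsd)
    return plan, grafted, mutated_seq
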