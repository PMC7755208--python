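"""Decoy-quality scores: radial-distribution-function ruggedness and
relative contact order.

The packing filter scores a model by how rugged its atomic radial
distribution function g(r) is at short range: well-packed cores show
sharp, reproducible coordination peaks below 4 Å, and the total
variation of g(r) over [0, 4] Å (a discrete form of the definite
integral of |dg/dr|) quantifies that.  Relative contact order is the
classic topology descriptor — mean sequence separation of atomic
contacts normalised by chain length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .structio import Chain, Structure

__all__ = ["RadialDistribution", "radial_distribution", "ruggedness",
           "contact_order", "heavy_atom_coords"]


@dataclass
class RadialDistribution:
    r_edges: np.ndarray  # bin edges, Å
    g: np.ndarray        # dimensionless g(r) per bin
    atom_count: int

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def ruggedness(self) -> float:
        return ruggedness(self)


def heavy_atom_coords(structure: Structure, selection: str = "heavy") -> np.ndarray:
    """Collect atom coordinates.

    ``selection``: 'heavy' = all non-hydrogen atoms (parsing already
    dropped hydrogens); 'sidechain' = heavy atoms outside the backbone
    (core packing view); 'CA' = alpha carbons.
    """
    backbone = {"N", "CA", "C", "O", "OXT"}
    coords = []
    for chain in structure.chains:
        for res in chain.residues:
            for name, xyz in res.atoms.items():
                if selection == "CA" and name != "CA":
                    continue
                if selection == "sidechain" and name in backbone:
                    continue
                coords.append(xyz)
    return np.asarray(coords, dtype=float)


def radial_distribution(structure: Structure | np.ndarray,
                        selection: str = "heavy",
                        bin_width: float = 0.1,
                        r_max: float = 10.0) -> RadialDistribution:
    """g(r) of the selected atoms.

    The pairwise-distance histogram is normalised by the spherical shell
    volume 4πr²Δr and by the ideal-gas pair density N(N−1)/(2·V), with V
    the volume of the bounding sphere (centroid to farthest atom), so
    that uniformly distributed points give g ≈ 1 at mid range.
    """
    if isinstance(structure, Structure):
        coords = heavy_atom_coords(structure, selection)
    else:
        coords = np.asarray(structure, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("radial distribution needs at least 2 atoms")
    d = pdist(coords)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * centers**2 * bin_width
    radius = float(np.max(np.linalg.norm(coords - coords.mean(axis=0), axis=1)))
    radius = max(radius, bin_width)  # degenerate single-point clouds
    volume = 4.0 / 3.0 * np.pi * radius**3
    density = n * (n - 1) / (2.0 * volume)
    g = hist / (shell * density)
    return RadialDistribution(r_edges=edges, g=g, atom_count=n)


def ruggedness(rd: RadialDistribution, r_upper: float = 4.0) -> float:
    """Total variation of g(r) over bin centers in [0, r_upper] Å."""
    centers = rd.r_centers
    if centers[-1] < r_upper:
        raise ValueError(
            f"radial distribution covers only {centers[-1]:.2f} Å "
            f"< required {r_upper} Å")
    mask = centers <= r_upper
    g = rd.g[mask]
    return float(np.sum(np.abs(np.diff(g))))


def contact_order(structure: Structure, chain_id: str | None = None,
                  cutoff: float = 6.0, min_separation: int = 2) -> float:
    """Relative contact order of one chain, in [0, 1].

    RCO = (1 / (L·N)) Σ_contacts |i − j| over heavy-atom pairs within
    ``cutoff`` Å whose residues are at least ``min_separation`` apart in
    sequence; N is the number of such atom pairs, L the chain length.
    """
    chain: Chain = structure[chain_id] if chain_id else structure.chains[0]
    L = len(chain)
    if L < min_separation + 1:
        raise ValueError("chain shorter than min_separation + 1")
    coords, res_idx = [], []
    for i, res in enumerate(chain.residues):
        for xyz in res.atoms.values():
            coords.append(xyz)
            res_idx.append(i)
    coords = np.asarray(coords)
    res_idx = np.asarray(res_idx)

    total, n_contacts = 0, 0
    # block over atoms to keep memory flat on big chains
    cutoff2 = cutoff * cutoff
    for a in range(0, len(coords), 2000):
        blk = coords[a:a + 2000]
        d2 = np.sum((blk[:, None, :] - coords[None, :, :]) ** 2, axis=2)
        sep = np.abs(res_idx[a:a + 2000, None] - res_idx[None, :])
        mask = (d2 <= cutoff2) & (sep >= min_separation)
        # count each unordered pair once
        gi = np.arange(a, a + len(blk))[:, None]
        mask &= gi < np.arange(len(coords))[None, :]
        n_contacts += int(mask.sum())
        total += int(sep[mask].sum())
    if n_contacts == 0:
        raise ValueError("no contacts found; contact order undefined")
    return total / (L * n_contacts)
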