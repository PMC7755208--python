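"""Ensemble deviation metrics.

Quantifies conformational spread of multi-model structures (NMR
ensembles, MD frame pools): RMSD of each model to the iteratively
superposed average structure, locally aligned epitope RMSD against a
reference, and cross-replica homogeneity of simulation repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import Structure, rmsd, superpose

__all__ = ["Ensemble", "mean_structure", "rmsd_to_mean",
           "local_epitope_rmsd", "replica_homogeneity"]

BACKBONE = ("N", "CA", "C")

#: fixed seed for cross-replica pair subsampling
_SUBSAMPLE_SEED = 1729


@dataclass
class Ensemble:
    """A set of models sharing residue topology (counts and names)."""

    models: list[Structure]
    label: str = ""

    def __post_init__(self):
        if len(self.models) < 2:
            raise ValueError("an ensemble needs at least 2 models")
        ref = self._topology(self.models[0])
        for m in self.models[1:]:
            if self._topology(m) != ref:
                raise ValueError(
                    f"model {m.id} topology differs from {self.models[0].id}")

    @staticmethod
    def _topology(st: Structure):
        return [(c.id, [(r.name, r.resseq, r.icode) for r in c.residues])
                for c in st.chains]

    def __len__(self):
        return len(self.models)

    def coords(self, atoms=BACKBONE, ranges=None) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinate stack over the selection."""
        return np.stack([model_coords(m, atoms, ranges) for m in self.models])


def model_coords(st: Structure, atoms=BACKBONE, ranges=None) -> np.ndarray:
    """Flattened atom coordinates of one model.

    ``ranges``: optional list of (chain_id, first_resseq, last_resseq)
    masks (inclusive, author numbering); default is every residue.
    Residues missing a requested atom are excluded — the same residues
    are excluded in every model of a topology-matched ensemble only if
    atoms are consistently absent, so prefer complete selections.
    """
    out = []
    for chain in st.chains:
        for res in chain.residues:
            if ranges is not None:
                if not any(cid == chain.id and lo <= res.resseq <= hi
                           for cid, lo, hi in ranges):
                    continue
            if all(a in res.atoms for a in atoms):
                out.extend(res.atoms[a] for a in atoms)
    return np.asarray(out, dtype=float)


def mean_structure(e: Ensemble, atoms=BACKBONE, ranges=None,
                   tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Iteratively superposed coordinate mean of the ensemble.

    Seeded by the first model; each round superposes every model onto
    the current mean and re-averages, until the mean moves < ``tol`` Å.
    """
    stack = e.coords(atoms, ranges)
    mean = stack[0].copy()
    for _ in range(max_iter):
        aligned = np.stack([superpose(x, mean).apply(x) for x in stack])
        new_mean = aligned.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            return mean
    raise RuntimeError(f"mean structure did not converge in {max_iter} iterations")


def rmsd_to_mean(e: Ensemble, atoms=BACKBONE, ranges=None
                 ) -> tuple[np.ndarray, float]:
    """Per-model RMSD to the average structure, and their mean."""
    mean = mean_structure(e, atoms, ranges)
    per_model = np.array([superpose(x, mean).rmsd
                          for x in e.coords(atoms, ranges)])
    return per_model, float(per_model.mean())


def local_epitope_rmsd(e: Ensemble, reference: Structure,
                       ref_ranges, model_ranges,
                       atoms=BACKBONE) -> tuple[np.ndarray, float]:
    """Locally aligned epitope RMSD of every model against a reference.

    Only the epitope stretches (``ref_ranges`` on the reference,
    ``model_ranges`` on the models, equal residue counts) are superposed
    and measured.  Returns per-model values and their average.
    """
    ref = model_coords(reference, atoms, ref_ranges)
    per_model = []
    for m in e.models:
        mob = model_coords(m, atoms, model_ranges)
        if mob.shape != ref.shape:
            raise ValueError(
                f"epitope selections differ in size: model {mob.shape} "
                f"vs reference {ref.shape}")
        per_model.append(superpose(mob, ref).rmsd)
    per_model = np.array(per_model)
    return per_model, float(per_model.mean())


def replica_homogeneity(replicas: list[Ensemble], atoms=BACKBONE,
                        ranges=None, pair_cap: int = 10_000) -> float:
    """Mean pairwise superposed RMSD across frames of *different* replicas.

    Lower values mean the repeats sample the same conformational basin.
    Above ``pair_cap`` cross pairs, a fixed-seed subsample is used.
    """
    if len(replicas) < 2:
        raise ValueError("need at least 2 replicas")
    stacks = [r.coords(atoms, ranges) for r in replicas]
    shape = stacks[0].shape[1:]
    if any(s.shape[1:] != shape for s in stacks):
        raise ValueError("replica topologies differ")

    pairs = [(a, i, b, j)
             for a in range(len(stacks)) for b in range(a + 1, len(stacks))
             for i in range(len(stacks[a])) for j in range(len(stacks[b]))]
    if len(pairs) > pair_cap:
        rng = np.random.default_rng(_SUBSAMPLE_SEED)
        idx = rng.choice(len(pairs), size=pair_cap, replace=False)
        pairs = [pairs[k] for k in idx]
    vals = [superpose(stacks[a][i], stacks[b][j]).rmsd
            for a, i, b, j in pairs]
    return float(np.mean(vals))
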