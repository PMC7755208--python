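"""De novo loop sequence enumeration and single-chain assembly.

Loops of 3–4 residues over the 9-letter design alphabet G, D, P, S, L,
N, T, E, K bridge a dimerisation interface, turning a homodimer into a
single-chain construct.  Conformational-stability ranking of the loops
is external (MD); scores are read back from a TSV and candidates ranked
ascending with lexicographic tie-break.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_ALPHABET = "GDPSLNTEK"

__all__ = ["LoopCandidate", "DEFAULT_ALPHABET", "enumerate_loops",
           "assemble_single_chain", "rank_candidates"]


@dataclass(frozen=True)
class LoopCandidate:
    sequence: str
    stability_score: float | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty loop sequence")
        bad = set(self.sequence) - set(DEFAULT_ALPHABET + "ACFHIMQRVWY")
        if bad:
            raise ValueError(f"non-amino-acid letters in loop: {sorted(bad)}")

    def __len__(self):
        return len(self.sequence)


def enumerate_loops(alphabet: str = DEFAULT_ALPHABET,
                    length: int = 3) -> list[LoopCandidate]:
    """All |alphabet|^length loop sequences, lexicographic in the given
    alphabet order, no duplicates."""
    if not alphabet:
        raise ValueError("empty alphabet")
    if len(set(alphabet)) != len(alphabet):
        raise ValueError("alphabet letters must be unique")
    if length < 1:
        raise ValueError("loop length must be >= 1")
    return [LoopCandidate("".join(p))
            for p in itertools.product(alphabet, repeat=length)]


def assemble_single_chain(chain_a: str, chain_b: str,
                          loop: LoopCandidate,
                          name: str = "single_chain") -> SeqRecord:
    """Concatenate A + loop + B into one FASTA record.

    The description records the junction indices (0-based, loop start
    and loop end exclusive) for provenance.
    """
    if not chain_a or not chain_b:
        raise ValueError("both chain sequences must be non-empty")
    seq = chain_a + loop.sequence + chain_b
    j0 = len(chain_a)
    j1 = j0 + len(loop)
    return SeqRecord(Seq(seq), id=name,
                     description=f"loop={loop.sequence} junction={j0}:{j1}")


def rank_candidates(candidates: list[LoopCandidate],
                    scores: dict[str, float]) -> list[LoopCandidate]:
    """Attach external stability scores and rank ascending (most stable
    first), lexicographic tie-break; unscored candidates sort last."""
    scored = [LoopCandidate(c.sequence, scores.get(c.sequence))
              for c in candidates]
    return sorted(scored, key=lambda c: (
        c.stability_score is None,
        c.stability_score if c.stability_score is not None else 0.0,
        c.sequence))
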