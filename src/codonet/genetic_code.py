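"""Genetic code tables and the sense-codon state space.

All substitution-model machinery works on an index space of *sense* codons
(61 states for the universal code).  Stop codons are excluded from the state
space entirely: coding alignments that contain one are rejected at parse
time, and the rate matrices never visit them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = "TCAG"
#: Purine/pyrimidine partners: a substitution is a transition iff it swaps
#: within {A, G} or within {C, T}.
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}

# Universal (standard) genetic code, codons in TCAG order (first position
# slowest), '*' marks stops.
_UNIVERSAL_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

MISSING = -1  # codon state for gaps / ambiguity codes


def is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITION_PAIRS


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus the sense-codon index it induces.

    Attributes
    ----------
    codon_to_aa:
        Mapping over all 64 triplets (one-letter amino acid, ``*`` = stop).
    sense_codons:
        Sense codons in fixed order; position = model state index.
    """

    codon_to_aa: dict[str, str]
    sense_codons: tuple[str, ...] = field(init=False)
    stop_codons: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map all 64 codons")
        sense = tuple(c for c in _all_codons() if self.codon_to_aa[c] != "*")
        stops = frozenset(c for c in _all_codons() if self.codon_to_aa[c] == "*")
        object.__setattr__(self, "sense_codons", sense)
        object.__setattr__(self, "stop_codons", stops)

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def index(self, codon: str) -> int:
        """State index of a sense codon (raises KeyError for stops)."""
        return self._index_map()[codon]

    def _index_map(self) -> dict[str, int]:
        # cached lazily on the instance's class-level dict keyed by id
        if not hasattr(self, "_idx"):
            object.__setattr__(
                self, "_idx", {c: i for i, c in enumerate(self.sense_codons)}
            )
        return self._idx  # type: ignore[attr-defined]

    def aa_of_state(self, state: int) -> str:
        return self.codon_to_aa[self.sense_codons[state]]

    def single_nt_changes(self) -> np.ndarray:
        """Structure matrix of single-nucleotide codon exchanges.

        Returns an (n, n) int8 array with 0 where codons differ at zero or
        more than one position, and otherwise a class code:
        1 synonymous transversion, 2 synonymous transition,
        3 nonsynonymous transversion, 4 nonsynonymous transition.
        """
        n = self.n_states
        out = np.zeros((n, n), dtype=np.int8)
        for i, ci in enumerate(self.sense_codons):
            for j, cj in enumerate(self.sense_codons):
                if i == j:
                    continue
                diff = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diff) != 1:
                    continue
                a, b = diff[0]
                ts = is_transition(a, b)
                syn = self.codon_to_aa[ci] == self.codon_to_aa[cj]
                out[i, j] = (1 if syn else 3) + (1 if ts else 0)
        return out


def _all_codons() -> list[str]:
    return ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)]


def universal_code() -> GeneticCode:
    """The standard genetic code (61 sense codons, stops TAA/TAG/TGA)."""
    return GeneticCode(dict(zip(_all_codons(), _UNIVERSAL_AA)))
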