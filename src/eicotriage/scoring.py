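"""Substitution scoring: BLOSUM62 in half-bit units, residue backgrounds.

The profile search and all similarity calls use BLOSUM62 with affine gap
penalties 11/1 — the documented defaults of the standard protein search
tools.  Selenocysteine (U) scores as cysteine throughout: U is chemically
cognate to C and is invisible to plain sequencing, so penalising it would
discard exactly the candidates the screening stage is designed to keep.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .io import ALPHABET

#: Robinson & Robinson amino-acid background frequencies, the convention
#: used by BLAST statistics.  U shares C's background; X gets a tiny mass.
ROBINSON_FREQUENCIES = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

#: The same 11/1 affine penalties expressed in bits, for use against
#: profiles whose columns are log-odds in bits (BLOSUM62 integers are in
#: half-bit units, so 11 half-bits = 5.5 bits).
PROFILE_GAP_OPEN_BITS = 5.5
PROFILE_GAP_EXTEND_BITS = 0.5


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue substitution score table over :data:`ALPHABET`."""

    name: str
    scores: np.ndarray  # (22, 22) float, index order = ALPHABET

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, float)
        if s.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError("score table must cover the full alphabet")
        if not np.allclose(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        for a in range(20):  # the 20 standard letters
            if s[a, a] <= 0:
                raise ValueError("self-scores must be positive")
        object.__setattr__(self, "scores", s)

    def score(self, a: str, b: str) -> float:
        return float(self.scores[ALPHABET.index(a), ALPHABET.index(b)])

    def index(self, letter: str) -> int:
        return ALPHABET.index(letter)


@lru_cache(maxsize=1)
def blosum62() -> SubstitutionMatrix:
    """BLOSUM62 extended over the pipeline alphabet (U scores as C)."""
    raw = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    table = np.zeros((n, n))
    # Proxy letters: U behaves as C; X uses BLOSUM62's own X column.
    proxy = {"U": "C"}
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            table[i, j] = raw[proxy.get(a, a), proxy.get(b, b)]
    return SubstitutionMatrix(name="BLOSUM62", scores=table)


@lru_cache(maxsize=1)
def background_frequencies() -> np.ndarray:
    """Background residue frequencies over :data:`ALPHABET`, summing to 1."""
    freqs = np.zeros(len(ALPHABET))
    for i, a in enumerate(ALPHABET):
        if a in ROBINSON_FREQUENCIES:
            freqs[i] = ROBINSON_FREQUENCIES[a]
        elif a == "U":
            freqs[i] = 1e-4
        elif a == "X":
            freqs[i] = 1e-4
    return freqs / freqs.sum()


@lru_cache(maxsize=1)
def blosum62_conditional() -> np.ndarray:
    """Conditional substitution probabilities q(a | b) implied by BLOSUM62.

    Derived from the half-bit scores by s(a,b) = 2*log2(p(a,b)/(f_a f_b)),
    so q(a|b) is proportional to f_a * 2**(s(a,b)/2), normalised per b.
    Used both for profile pseudocounts and for the family simulator's
    substitution model, which keeps planted identities meaningful under the
    search scoring.
    """
    m = blosum62().scores
    bg = background_frequencies()
    joint = bg[:, None] * np.power(2.0, m / 2.0)
    cond = joint / joint.sum(axis=0, keepdims=True)
    return cond
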