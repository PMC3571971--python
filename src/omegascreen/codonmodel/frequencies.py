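"""Stationary codon frequency models: equal, F3x4, F61.

The frequency model is a nuisance choice of the likelihood machinery; F3x4
(codon frequencies from position-specific nucleotide frequencies) is the
conventional default of codon-model software and is estimated empirically
from the alignment being analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..genetics import MISSING, N_CODONS, NUCLEOTIDES, SENSE_CODONS

_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
# codon -> (nt at pos0, nt at pos1, nt at pos2) as indices, for F3x4
_CODON_NT = np.array(
    [[_NT_INDEX[c[p]] for p in range(3)] for c in SENSE_CODONS], dtype=np.intp
)

_MIN_FREQ = 1e-10


@dataclass(frozen=True)
class CodonFrequencies:
    method: str  # "equal" | "F3x4" | "F61"
    pi: np.ndarray  # 61-vector, sums to 1, all > 0

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (N_CODONS,):
            raise ValueError(f"pi must have length {N_CODONS}")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be nonnegative and sum to 1")
        object.__setattr__(self, "pi", pi / pi.sum())

    @classmethod
    def equal(cls) -> "CodonFrequencies":
        return cls("equal", np.full(N_CODONS, 1.0 / N_CODONS))

    @classmethod
    def from_pi(cls, pi, method: str = "custom") -> "CodonFrequencies":
        return cls(method, np.asarray(pi, dtype=float))

    @classmethod
    def f3x4(cls, codes: np.ndarray) -> "CodonFrequencies":
        """F3x4 from observed position-specific nucleotide frequencies.

        ``codes`` is any integer array of codon states; MISSING entries are
        ignored. Stop codons are excluded by renormalizing over the 61
        sense codons.
        """
        obs = codes[codes != MISSING]
        if obs.size == 0:
            return cls.equal()
        counts = np.zeros((3, 4))
        for p in range(3):
            nts = _CODON_NT[obs, p]
            counts[p] = np.bincount(nts, minlength=4)
        freqs = (counts + 0.0) / counts.sum(axis=1, keepdims=True)
        pi = freqs[0, _CODON_NT[:, 0]] * freqs[1, _CODON_NT[:, 1]] * freqs[2, _CODON_NT[:, 2]]
        pi = np.maximum(pi, _MIN_FREQ)
        return cls("F3x4", pi / pi.sum())

    @classmethod
    def f3x4_from_nucleotide_freqs(cls, freqs: np.ndarray) -> "CodonFrequencies":
        """F3x4 from given (3 x 4) or (4,) nucleotide frequencies (ACGT order)."""
        freqs = np.asarray(freqs, dtype=float)
        if freqs.ndim == 1:
            freqs = np.tile(freqs, (3, 1))
        pi = freqs[0, _CODON_NT[:, 0]] * freqs[1, _CODON_NT[:, 1]] * freqs[2, _CODON_NT[:, 2]]
        pi = np.maximum(pi, _MIN_FREQ)
        return cls("F3x4", pi / pi.sum())

    @classmethod
    def f61(cls, codes: np.ndarray, pseudocount: float = 1.0) -> "CodonFrequencies":
        """Empirical codon frequencies with a pseudocount floor."""
        obs = codes[codes != MISSING]
        counts = np.bincount(obs, minlength=N_CODONS).astype(float) + pseudocount
        return cls("F61", counts / counts.sum())


def resolve_frequencies(method: str, codes: np.ndarray) -> CodonFrequencies:
    """Build frequencies of the requested kind from alignment data."""
    if method == "equal":
        return CodonFrequencies.equal()
    if method == "F3x4":
        return CodonFrequencies.f3x4(codes)
    if method == "F61":
        return CodonFrequencies.f61(codes)
    raise ValueError(f"unknown frequency model {method!r}")
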