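"""Standard nuclear genetic code on the 61 sense codons.

The codon-model state space excludes the three stop codons entirely (rather
than carrying them with rate zero), which is appropriate for nuclear
protein-coding genes. Codons are indexed lexicographically over the
nucleotide order A, C, G, T; all downstream modules refer to codons by these
integer state indices.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: tuple[str, ...] = tuple(sorted(_standard.stop_codons))

#: the 61 sense codons in lexicographic (A<C<G<T) order
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in _standard.stop_codons
)

N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid encoded by each sense codon, aligned with SENSE_CODONS
AMINO_ACIDS: tuple[str, ...] = tuple(_standard.forward_table[c] for c in SENSE_CODONS)

MISSING = -1  # state code for a missing/masked codon

_transition_pairs = {frozenset("AG"), frozenset("CT")}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return frozenset((a, b)) in _transition_pairs


def _build_pair_tables():
    """Enumerate all ordered sense-codon pairs differing at one position.

    Returns index arrays (i, j) plus boolean transition / synonymous flags,
    the combinatorial skeleton of the codon rate matrix.
    """
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append(is_transition(ci[p], cj[p]))
            syn.append(AMINO_ACIDS[i] == AMINO_ACIDS[j])
    return (
        np.array(ii, dtype=np.intp),
        np.array(jj, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
    )


PAIR_I, PAIR_J, PAIR_IS_TRANSITION, PAIR_IS_SYNONYMOUS = _build_pair_tables()


def codons_to_indices(seq: str) -> np.ndarray:
    """Translate a gap-free nucleotide string into codon state indices.

    Codons containing anything other than A/C/G/T, and stop codons, map to
    MISSING. Length must be a multiple of 3.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    seq = seq.upper()
    out = np.empty(len(seq) // 3, dtype=np.int16)
    for k in range(out.size):
        out[k] = CODON_INDEX.get(seq[3 * k : 3 * k + 3], MISSING)
    return out


def indices_to_codons(idx: np.ndarray, missing: str = "NNN") -> str:
    """Inverse of :func:`codons_to_indices`; MISSING renders as ``missing``."""
    return "".join(missing if i == MISSING else SENSE_CODONS[i] for i in idx)


# Synonymous-family structure, used for RSCU / codon-usage statistics.
# Families keyed by amino acid; single-codon families (Met, Trp) carry no
# usage information and are excluded from RSCU by the caller.
SYNONYMOUS_FAMILIES: dict[str, tuple[int, ...]] = {}
for _i, _aa in enumerate(AMINO_ACIDS):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] = SYNONYMOUS_FAMILIES[_aa] + (_i,)
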