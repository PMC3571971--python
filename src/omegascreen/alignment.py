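"""Codon alignment container and FASTA round-tripping.

A :class:`CodonAlignment` stores one gene's alignment as an integer matrix
(taxa x codon sites) over the 61 sense-codon states, with ``MISSING`` (-1)
for masked or absent data. Coordinates are 0-based and half-open internally;
log messages report 1-based columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import MISSING, codons_to_indices, indices_to_codons


@dataclass
class CodonAlignment:
    gene_id: str
    taxa: list[str]
    codes: np.ndarray  # (n_taxa, n_codons) int16, values in {-1, 0..60}
    #: codon offsets of gene boundaries after concatenation (half-open)
    boundaries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, n_codons)")
        if not self.boundaries:
            self.boundaries = [(self.gene_id, 0, self.n_codons)]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.codes.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.taxa.index(taxon)]

    # ---------------------------------------------------------------- I/O

    @classmethod
    def from_sequences(cls, gene_id: str, seqs: dict[str, str]) -> "CodonAlignment":
        """Build from gap-free nucleotide strings of equal length.

        Non-ACGT codons and stop codons become MISSING.
        """
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"{gene_id}: unequal sequence lengths {sorted(lengths)}")
        codes = np.vstack([codons_to_indices(seqs[t]) for t in taxa])
        return cls(gene_id, taxa, codes)

    @classmethod
    def read_fasta(cls, path: str | Path, gene_id: str | None = None) -> "CodonAlignment":
        path = Path(path)
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise ValueError(f"{path}: no FASTA records")
        return cls.from_sequences(gene_id or path.stem, seqs)

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(indices_to_codons(self.codes[i])), id=t, description="")
            for i, t in enumerate(self.taxa)
        ]
        SeqIO.write(records, str(path), "fasta")

    # ------------------------------------------------------------ utility

    def reorder(self, taxa: list[str]) -> "CodonAlignment":
        """Return a copy with rows in the given taxon order."""
        if set(taxa) != set(self.taxa):
            raise ValueError("taxon set mismatch")
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(self.gene_id, list(taxa), self.codes[idx].copy(),
                              list(self.boundaries))

    def take_columns(self, cols: np.ndarray) -> "CodonAlignment":
        return CodonAlignment(self.gene_id, list(self.taxa), self.codes[:, cols])

    def complete_column_mask(self) -> np.ndarray:
        """Boolean mask of codon columns with data for every taxon."""
        return (self.codes != MISSING).all(axis=0)


def concatenate_alignments(
    alignments: list[CodonAlignment], taxa: list[str] | None = None,
    gene_id: str = "concat",
) -> CodonAlignment:
    """Column-wise concatenation of alignments over an identical taxon set.

    Gene boundary offsets are recorded so per-gene regions remain addressable.
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    if taxa is None:
        taxa = list(alignments[0].taxa)
    rows = []
    boundaries = []
    offset = 0
    for aln in alignments:
        if set(aln.taxa) != set(taxa):
            raise ValueError(
                f"{aln.gene_id}: taxon set {sorted(aln.taxa)} != {sorted(taxa)}"
            )
        rows.append(aln.reorder(taxa).codes)
        boundaries.append((aln.gene_id, offset, offset + aln.n_codons))
        offset += aln.n_codons
    return CodonAlignment(gene_id, list(taxa), np.hstack(rows), boundaries)
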