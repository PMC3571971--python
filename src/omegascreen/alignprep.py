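"""Alignment preparation: consensus merging, codon masking, column filtering.

Inputs are pre-aligned per-gene nucleotide fragments in the coordinate
system of a reference alignment (gaps as ``-``). The stages turn them into
clean codon alignments for likelihood analysis:

1. merge overlapping fragments of one taxon into a single consensus row,
   resolving conflicts by sequence-quality tokens (contig size, then
   fragment length, then input order — a declared convention);
2. drop frameshifting insert columns relative to the reference and mask
   incomplete codons and premature stop codons as missing data (a terminal
   stop codon is removed, i.e. not treated as an error);
3. keep only gap-less codon columns with data from every taxon (the 4-way
   screen) or, for deeper candidate-gene alignments, columns with data from
   at least half the taxa.

Coordinates are 0-based half-open internally; log messages are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import CodonAlignment, concatenate_alignments  # noqa: F401 (re-export)
from .genetics import CODON_INDEX, MISSING, STOP_CODONS

logger = logging.getLogger(__name__)

GAP = "-"


class GeneExcludedError(ValueError):
    """Raised when filtering leaves nothing analyzable for a gene."""


@dataclass
class AlignedFragment:
    gene_id: str
    taxon: str
    sequence: str       # aligned to the reference; '-' where no data
    contig_size: int = 1
    fragment_length: int | None = None  # defaults to non-gap length

    def __post_init__(self):
        if self.fragment_length is None:
            self.fragment_length = sum(1 for c in self.sequence if c != GAP)


def merge_fragments_to_consensus(fragments: list[AlignedFragment]) -> str:
    """Merge one gene+taxon's fragments into a single aligned consensus row.

    Columns covered by exactly one fragment take its base. Conflicting
    overlaps are resolved by larger contig size, then longer fragment
    length, then input order.
    """
    if not fragments:
        raise ValueError("need at least one fragment")
    length = len(fragments[0].sequence)
    if any(len(f.sequence) != length for f in fragments):
        raise ValueError("fragments must share the reference alignment length")
    # sort once by quality (stable, so input order breaks remaining ties)
    ranked = sorted(
        enumerate(fragments),
        key=lambda kv: (-kv[1].contig_size, -kv[1].fragment_length, kv[0]),
    )
    out = [GAP] * length
    for _, frag in reversed([r for r in ranked]):
        for i, base in enumerate(frag.sequence):
            if base != GAP:
                out[i] = base  # later (better-ranked) fragments overwrite
    return "".join(out)


def mask_invalid_codons(row: str, reference: str | None = None, frame: int = 0) -> str:
    """Return a frame-clean nucleotide row with invalid codons masked as NNN.

    If ``reference`` is given, columns where the reference has a gap
    (inserts relative to the reference) are removed first, restoring the
    downstream reading frame. Codons containing gaps or ambiguity codes and
    in-frame premature stop codons become NNN; a terminal stop codon is
    removed (masked without complaint). Bases outside complete codons of
    the given frame are dropped.
    """
    if reference is not None:
        if len(reference) != len(row):
            raise ValueError("row and reference lengths differ")
        row = "".join(b for b, r in zip(row, reference) if r != GAP)
    row = row[frame:]
    row = row[: len(row) - len(row) % 3]
    codons = [row[i : i + 3] for i in range(0, len(row), 3)]
    out = []
    for k, codon in enumerate(codons):
        cu = codon.upper()
        if cu in STOP_CODONS:
            out.append("NNN")  # terminal stop removed; premature stop masked
            if k != len(codons) - 1:
                logger.debug("premature stop codon masked at codon %d", k + 1)
        elif cu in CODON_INDEX:
            out.append(cu)
        else:
            out.append("NNN")
    return "".join(out)


def filter_complete_codon_columns(alignment: CodonAlignment) -> CodonAlignment:
    """Keep exactly the codon columns where every taxon has a sense codon.

    Raises :class:`GeneExcludedError` when nothing survives, mirroring the
    exclusion of genes without any region covered by all taxa.
    """
    mask = alignment.complete_column_mask()
    n_kept = int(mask.sum())
    if n_kept == 0:
        raise GeneExcludedError(
            f"{alignment.gene_id}: no codon column with data from all "
            f"{alignment.n_taxa} taxa"
        )
    logger.info(
        "%s: retained %d/%d codon columns (%.1f%%)",
        alignment.gene_id, n_kept, alignment.n_codons,
        100.0 * n_kept / alignment.n_codons,
    )
    return alignment.take_columns(np.flatnonzero(mask))


def trim_for_site_analysis(
    alignment: CodonAlignment, min_taxon_fraction: float = 0.5
) -> CodonAlignment:
    """Drop codon columns with data from fewer than half the taxa.

    Columns with exactly half the taxa are retained (boundary rule).
    Remaining missing entries stay; the pruning likelihood handles them.
    """
    present = (alignment.codes != MISSING).sum(axis=0)
    keep = present >= min_taxon_fraction * alignment.n_taxa - 1e-9
    if not keep.any():
        raise GeneExcludedError(f"{alignment.gene_id}: no column passes trimming")
    return alignment.take_columns(np.flatnonzero(keep))
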