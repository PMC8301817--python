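"""Alignment post-processing for tree building.

Two operations used to prepare supermatrices for phylogenetic
inference: gap-frequency column trimming (the ``trimal -gt`` rule: a
column is kept iff its fraction of non-gap characters is at least the
threshold) and concatenation of per-marker alignments into a
supermatrix with all-gap blocks for taxa missing from a marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


@dataclass
class AlignmentMatrix:
    """Equal-length aligned rows keyed by unique taxon ids."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows are not equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass(frozen=True)
class TrimParams:
    """Keep a column iff its non-gap fraction >= gap_threshold."""

    gap_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.gap_threshold <= 1.0):
            raise ValueError("gap_threshold must be in [0, 1]")


def trim_gap_columns(aln: AlignmentMatrix,
                     params: TrimParams = TrimParams()) -> AlignmentMatrix:
    """Drop high-gap columns; idempotent, order-preserving."""
    if not aln.rows or aln.n_columns == 0:
        raise ValueError("cannot trim an empty alignment")
    arr = np.array([list(r) for r in aln.rows])
    nongap_frac = (arr != GAP).mean(axis=0)
    keep = nongap_frac >= params.gap_threshold
    trimmed = ["".join(row) for row in arr[:, keep]]
    return AlignmentMatrix(list(aln.taxa), trimmed)


def concatenate_alignments(alignments: list[AlignmentMatrix],
                           taxa: list[str],
                           names: list[str] | None = None
                           ) -> tuple[AlignmentMatrix,
                                      list[tuple[str, int, int]]]:
    """Concatenate marker alignments into a supermatrix.

    A taxon absent from a marker contributes an all-gap block.  Returns
    the supermatrix over the master taxon list plus the block boundaries
    as (marker name, start, end), 1-based inclusive.
    """
    if names is None:
        names = [f"marker{i + 1}" for i in range(len(alignments))]
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    blocks: list[tuple[str, int, int]] = []
    pos = 1
    for name, aln in zip(names, alignments):
        missing = set(aln.taxa) - set(taxa)
        if missing:
            raise ValueError(f"marker taxa not in master list: {missing}")
        width = aln.n_columns
        for t in taxa:
            parts[t].append(aln.row(t) if t in aln.taxa else GAP * width)
        blocks.append((name, pos, pos + width - 1))
        pos += width
    rows = ["".join(parts[t]) for t in taxa]
    return AlignmentMatrix(list(taxa), rows), blocks


def slice_block(aln: AlignmentMatrix, start: int, end: int
                ) -> AlignmentMatrix:
    """Extract columns start..end (1-based inclusive)."""
    return AlignmentMatrix(list(aln.taxa),
                           [r[start - 1:end] for r in aln.rows])


# ---------------------------------------------------------------------------
# FASTA alignment I/O and RAxML-style partition files

def read_alignment_fasta(path: str) -> AlignmentMatrix:
    taxa, rows = [], []
    for rec in SeqIO.parse(path, "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).replace(".", GAP))  # '.' normalized on read
    return AlignmentMatrix(taxa, rows)


def write_alignment_fasta(aln: AlignmentMatrix, path: str) -> None:
    SeqIO.write([SeqRecord(Seq(r), id=t, description="")
                 for t, r in zip(aln.taxa, aln.rows)], path, "fasta")


def write_partitions(blocks: list[tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for name, start, end in blocks:
            fh.write(f"LG, {name} = {start}-{end}\n")


def read_partitions(path: str) -> list[tuple[str, int, int]]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            _, _, spec = line.partition(",")
            name, _, span = spec.partition("=")
            start, _, end = span.partition("-")
            blocks.append((name.strip(), int(start), int(end)))
    return blocks
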