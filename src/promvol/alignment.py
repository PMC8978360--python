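"""Multi-species alignment blocks with coordinate projection.

Blocks mirror MAF ``a``/``s`` records: each species row carries a source
name (``species.chrom``), a 0-based start on that species' sequence, an
aligned (gapped) text, strand and source length. The human row is the
reference for projection: a human genomic position maps to an alignment
column, and any other row is "aligned" there iff its text has a non-gap
character in that column.

I/O goes through Bio.AlignIO's MAF support; this module only adds the
projection logic the turnover classification and ancestral-state resolution
need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: outgroup species in increasing phylogenetic distance from human, used when
#: a block carries no explicit ancestral row
ANCESTRAL_PREFERENCE = ("ancestral", "mouse", "dog", "horse", "cow", "pig")
OUTGROUPS = ("dog", "horse", "cow", "pig")


@dataclass
class SpeciesRow:
    """One gapped sequence of an alignment block."""

    src: str          # "species.chrom"
    start: int        # 0-based start on the source sequence (+ strand)
    text: str         # aligned sequence with '-' gaps
    strand: str = "+"
    src_size: int = 0

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) > 1 else ""

    @property
    def size(self) -> int:
        return len(self.text) - self.text.count(GAP)


@dataclass
class AlignmentBlock:
    """A gapped multi-species alignment block (one MAF ``a`` record)."""

    rows: dict[str, SpeciesRow] = field(default_factory=dict)
    ref_species: str = "human"

    def __post_init__(self):
        widths = {len(r.text) for r in self.rows.values()}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment block: row widths {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())).text) if self.rows else 0

    @property
    def ref_row(self) -> SpeciesRow:
        return self.rows[self.ref_species]

    @property
    def ref_chrom(self) -> str:
        return self.ref_row.chrom

    @property
    def ref_start(self) -> int:
        return self.ref_row.start

    @property
    def ref_end(self) -> int:
        return self.ref_row.start + self.ref_row.size

    def _ref_col_positions(self) -> np.ndarray:
        """Reference genomic position per column; -1 at reference gaps."""
        text = np.frombuffer(self.ref_row.text.encode(), dtype="S1")
        nongap = text != GAP.encode()
        pos = np.cumsum(nongap) - 1 + self.ref_row.start
        pos[~nongap] = -1
        return pos

    def column_of(self, ref_pos: int) -> int | None:
        """Alignment column holding the given reference position, or None."""
        if not (self.ref_start <= ref_pos < self.ref_end):
            return None
        cols = np.nonzero(self._ref_col_positions() == ref_pos)[0]
        return int(cols[0]) if cols.size else None

    def is_aligned(self, species: str, ref_pos: int) -> bool:
        """True iff `species` has a non-gap character at the column of ref_pos."""
        if species not in self.rows:
            return False
        col = self.column_of(ref_pos)
        if col is None:
            return False
        return self.rows[species].text[col] != GAP

    def species_position(self, species: str, ref_pos: int) -> int | None:
        """Project a reference position onto another species' coordinates.

        Returns the 0-based source position of the character aligned to
        ``ref_pos``, or None if that row is gapped there (or absent).
        """
        if species not in self.rows:
            return None
        col = self.column_of(ref_pos)
        if col is None:
            return None
        row = self.rows[species]
        if row.text[col] == GAP:
            return None
        return row.start + sum(1 for c in row.text[:col] if c != GAP)

    def window_columns(self, ref_lo: int, ref_hi: int) -> tuple[int, int] | None:
        """Column span [c0, c1] covering reference interval [ref_lo, ref_hi]
        inclusive, including any inserted (reference-gap) columns inside it."""
        c0 = self.column_of(ref_lo)
        c1 = self.column_of(ref_hi)
        if c0 is None or c1 is None:
            return None
        return c0, c1

    def ancestral_source(self) -> str | None:
        """Row supplying the ancestral state: an explicit 'ancestral' row if
        present, else the closest outgroup present in the block."""
        for sp in ANCESTRAL_PREFERENCE:
            if sp in self.rows:
                return sp
        return None


class AlignmentIndex:
    """Blocks indexed by reference chromosome for point queries."""

    def __init__(self, blocks: list[AlignmentBlock]):
        self._by_chrom: dict[str, list[AlignmentBlock]] = {}
        for b in blocks:
            self._by_chrom.setdefault(b.ref_chrom, []).append(b)
        self._starts: dict[str, np.ndarray] = {}
        self._max_width: dict[str, int] = {}
        for chrom, bl in self._by_chrom.items():
            bl.sort(key=lambda b: b.ref_start)
            self._starts[chrom] = np.array([b.ref_start for b in bl])
            self._max_width[chrom] = max(b.ref_end - b.ref_start for b in bl)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)

    def covering(self, chrom: str, pos: int) -> list[AlignmentBlock]:
        """All blocks whose reference span contains `pos`."""
        if chrom not in self._by_chrom:
            return []
        bl = self._by_chrom[chrom]
        starts = self._starts[chrom]
        hi = int(np.searchsorted(starts, pos, side="right"))
        lo = int(np.searchsorted(starts, pos - self._max_width[chrom], side="left"))
        return [b for b in bl[lo:hi] if b.ref_end > pos]


def read_maf(path: str | Path, ref_species: str = "human") -> list[AlignmentBlock]:
    """Read alignment blocks from a MAF file (via Bio.AlignIO)."""
    blocks = []
    for aln in AlignIO.parse(str(path), "maf"):
        rows = {}
        for rec in aln:
            ann = rec.annotations
            row = SpeciesRow(
                src=rec.id,
                start=int(ann.get("start", 0)),
                text=str(rec.seq).upper(),
                strand="+" if ann.get("strand", 1) == 1 else "-",
                src_size=int(ann.get("srcSize", 0)),
            )
            rows[row.species] = row
        blocks.append(AlignmentBlock(rows=rows, ref_species=ref_species))
    return blocks


def write_maf(blocks: list[AlignmentBlock], path: str | Path) -> None:
    """Write alignment blocks as MAF (via Bio.AlignIO)."""
    alns = []
    for b in blocks:
        recs = []
        for row in b.rows.values():
            rec = SeqRecord(Seq(row.text), id=row.src, description="")
            rec.annotations.update(
                start=row.start,
                size=row.size,
                strand=1 if row.strand == "+" else -1,
                srcSize=row.src_size or (row.start + row.size),
            )
            recs.append(rec)
        alns.append(MultipleSeqAlignment(recs))
    AlignIO.write(alns, str(path), "maf")
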