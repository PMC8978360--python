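"""Evolutionary-history classification of promoters and covariate annotation.

A promoter's history is resolved from whole-genome alignment blocks and
mouse promoter activity calls:

* **conserved** — the representative TSS position aligns to mouse and the
  projected mouse position lies within 50 bp of a robust mouse promoter;
* **functional_turnover** — aligns to mouse but is more than 50 bp from both
  robust and permissive mouse promoters;
* **human_inserted** — does not align to mouse nor to any of the outgroups
  (dog, horse, cow, pig): the sequence arose on the human lineage;
* **mouse_deleted** — does not align to mouse but aligns to at least one
  outgroup: the sequence was ancestrally present and lost in mouse;
* **unclassified** — aligns to mouse, more than 50 bp from a robust promoter
  but within 50 bp of a permissive-only one (excluded downstream), or the
  promoter's chromosome is absent from the alignment index.

The annotation helpers compute the regression covariates: GC count, CpG
island / repeat overlap, a TATA-box scan with an exact-enumeration p-value,
and the isoform count of the linked gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentIndex, OUTGROUPS
from .intervals import intervals_overlap_any, merge_intervals, nearest_edge_distance

logger = logging.getLogger(__name__)

HISTORY_LABELS = ("conserved", "functional_turnover", "human_inserted",
                  "mouse_deleted", "unclassified")

#: distance rule for promoter activity conservation (inclusive, bp)
MOUSE_PROMOTER_MAX_DIST = 50


@dataclass
class Promoter:
    """A strand-aware TSS interval (CAGE tag-cluster span) with features."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    tss: int | None = None          # representative position; cluster midpoint default
    history: str = "unclassified"
    gc_count: int = 0
    cpg_overlap: bool = False
    tata: bool = False
    repeat_overlap: bool = False
    isoform_count: int = 0
    gene_id: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"promoter {self.id}: start must be < end")
        if self.tss is None:
            self.tss = (self.start + self.end) // 2
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"promoter {self.id}: tss outside cluster span")


class MousePromoterSet:
    """Robust and permissive mouse promoter intervals, indexed by position."""

    def __init__(self, robust: pd.DataFrame, permissive: pd.DataFrame):
        self._sets = {}
        for name, df in (("robust", robust), ("permissive", permissive)):
            by_chrom = {}
            if len(df):
                for chrom, sub in df.groupby("chrom"):
                    by_chrom[chrom] = merge_intervals(sub["start"].to_numpy(),
                                                      sub["end"].to_numpy())
            self._sets[name] = by_chrom

    def distance(self, which: str, chrom: str, pos: int) -> float:
        """Distance from a mouse position to the nearest promoter edge."""
        by_chrom = self._sets[which]
        if chrom not in by_chrom:
            return math.inf
        s, e = by_chrom[chrom]
        return float(nearest_edge_distance(np.array([pos]), s, e)[0])


def classify_promoter(promoter: Promoter, alignments: AlignmentIndex,
                      mouse_promoters: MousePromoterSet,
                      max_dist: int = MOUSE_PROMOTER_MAX_DIST) -> str:
    """Resolve one promoter's evolutionary history label."""
    if promoter.chrom not in alignments.chromosomes:
        logger.warning("promoter %s: chromosome %s absent from alignment index",
                       promoter.id, promoter.chrom)
        return "unclassified"
    pos = promoter.tss
    blocks = alignments.covering(promoter.chrom, pos)
    mouse_hit = None  # (mouse chrom, mouse position)
    for b in blocks:
        mpos = b.species_position("mouse", pos)
        if mpos is not None:
            mouse_hit = (b.rows["mouse"].chrom, mpos)
            break
    if mouse_hit is not None:
        d_robust = mouse_promoters.distance("robust", *mouse_hit)
        if d_robust <= max_dist:
            return "conserved"
        d_perm = mouse_promoters.distance("permissive", *mouse_hit)
        if d_perm > max_dist:
            return "functional_turnover"
        return "unclassified"  # permissive-only neighbourhood: dropped downstream
    for b in blocks:
        for sp in OUTGROUPS:
            if b.is_aligned(sp, pos):
                return "mouse_deleted"
    return "human_inserted"


def classify_promoters(promoters: pd.DataFrame, alignments: AlignmentIndex,
                       mouse_promoters: MousePromoterSet,
                       max_dist: int = MOUSE_PROMOTER_MAX_DIST) -> pd.DataFrame:
    """Vectorized driver: adds a ``history`` column to a promoter table."""
    out = promoters.copy()
    labels = []
    for rec in out.itertuples(index=False):
        tss = int(getattr(rec, "tss", (rec.start + rec.end) // 2))
        p = Promoter(id=str(rec.id), chrom=rec.chrom, start=int(rec.start),
                     end=int(rec.end), strand=getattr(rec, "strand", "+"), tss=tss)
        labels.append(classify_promoter(p, alignments, mouse_promoters, max_dist))
    out["history"] = labels
    return out


# ---------------------------------------------------------------------------
# Sequence features

def compute_gc_count(sequence: str) -> int:
    """Number of G and C nucleotides in a cluster sequence (N contributes 0)."""
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return seq.count("G") + seq.count("C")


# A TBP-binding-site-like position count matrix (8 columns, TATAWAWR
# consensus). Synthetic: hand-curated to the canonical TATA-box shape, not
# taken from any motif database.
TATA_PWM_COUNTS = np.array([
    #  A    C    G    T
    [  5,   5,   5,  85],
    [ 85,   5,   5,   5],
    [  5,   5,   5,  85],
    [ 85,   5,   5,   5],
    [ 60,   5,   5,  30],
    [ 85,   5,   5,   5],
    [ 60,   5,   5,  30],
    [ 45,   5,  45,   5],
], dtype=float)

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _pwm_log_odds(pwm_counts: np.ndarray, background: np.ndarray) -> np.ndarray:
    probs = (pwm_counts + 0.25) / (pwm_counts + 0.25).sum(axis=1, keepdims=True)
    return np.log2(probs / background)


def _score_distribution(log_odds: np.ndarray, background: np.ndarray):
    """Exact distribution of PWM scores over all 4^k k-mers under a 0-order
    background: enumeration by iterated outer sums."""
    scores = np.zeros(1)
    probs = np.ones(1)
    for col in log_odds:
        scores = (scores[:, None] + col[None, :]).ravel()
        probs = (probs[:, None] * background[None, :]).ravel()
    return scores, probs


def _pwm_pvalue(score: float, scores: np.ndarray, probs: np.ndarray) -> float:
    return float(probs[scores >= score - 1e-12].sum())


def scan_tata(upstream_sequence: str, pwm: np.ndarray | None = None,
              p_threshold: float = 1e-3) -> bool:
    """TATA-box presence in the -30..-20 upstream region.

    `upstream_sequence` is the region scanned (both strands, every full
    window); callers pass the sequence covering offsets -30..-20 upstream
    of the TSS extended by the motif length. A window is a hit when its
    score's exact-enumeration p-value under a 0-order background estimated
    from the scanned sequence falls below `p_threshold`.
    """
    pwm = TATA_PWM_COUNTS if pwm is None else np.asarray(pwm, dtype=float)
    k = pwm.shape[0]
    seq = upstream_sequence.upper()
    if len(seq) < k:
        raise ValueError(f"scanned window ({len(seq)} nt) shorter than motif ({k} nt)")
    if p_threshold <= 0:
        return False
    counts = np.array([seq.count(b) for b in "ACGT"], dtype=float)
    if counts.sum() == 0 or (counts == 0).any():
        background = np.full(4, 0.25)   # uniform fallback
    else:
        background = counts / counts.sum()
    log_odds = _pwm_log_odds(pwm, background)
    scores, probs = _score_distribution(log_odds, background)
    for strand_seq in (seq, seq.translate(_COMPLEMENT)[::-1]):
        for i in range(len(strand_seq) - k + 1):
            window = strand_seq[i: i + k]
            if any(b not in _BASE_INDEX for b in window):
                continue
            s = sum(log_odds[j, _BASE_INDEX[b]] for j, b in enumerate(window))
            if _pwm_pvalue(s, scores, probs) < p_threshold:
                return True
    return False


def annotate_overlaps(promoters: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean per promoter: >=1 bp overlap with any interval (half-open)."""
    flags = np.zeros(len(promoters), dtype=bool)
    if len(intervals) == 0 or len(promoters) == 0:
        return flags
    merged = {chrom: merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
              for chrom, sub in intervals.groupby("chrom")}
    for chrom, sub in promoters.groupby("chrom"):
        if chrom not in merged:
            continue
        s, e = merged[chrom]
        idx = sub.index.to_numpy()
        flags[promoters.index.get_indexer(idx)] = intervals_overlap_any(
            sub["start"].to_numpy(), sub["end"].to_numpy(), s, e)
    return flags


def assign_isoform_count(promoters: pd.DataFrame,
                         gene_models: pd.DataFrame) -> pd.DataFrame:
    """Isoform count of each promoter's parent gene.

    Promoters without a gene link, or linked to a gene absent from the gene
    models, get count 0 and ``isoform_flagged=True``.
    """
    counts = gene_models.groupby("gene_id")["transcript_id"].nunique()
    out = promoters.copy()
    gene = out.get("gene_id")
    if gene is None:
        out["isoform_count"] = 0
        out["isoform_flagged"] = True
        return out
    mapped = gene.map(counts)
    out["isoform_count"] = mapped.fillna(0).astype(int)
    out["isoform_flagged"] = mapped.isna() | gene.isna()
    return out


def annotate_promoters(promoters: pd.DataFrame, alignments: AlignmentIndex,
                       *, cpg_islands: pd.DataFrame | None = None,
                       repeats: pd.DataFrame | None = None,
                       gene_models: pd.DataFrame | None = None,
                       tata_threshold: float = 1e-3) -> pd.DataFrame:
    """Attach sequence and gene covariates to a classified promoter table.

    Promoter and upstream sequences are taken from the human row of the
    covering alignment block; promoters not covered get gc_count 0 and
    tata False.
    """
    out = promoters.copy()
    gc, tata = [], []
    for rec in out.itertuples(index=False):
        tss = int(getattr(rec, "tss", (rec.start + rec.end) // 2))
        seq = _human_sequence(alignments, rec.chrom, int(rec.start), int(rec.end))
        gc.append(compute_gc_count(seq) if seq else 0)
        k = TATA_PWM_COUNTS.shape[0]
        if rec.strand == "-":
            lo, hi = tss + 20 - (k - 1), tss + 31
        else:
            lo, hi = tss - 30, tss - 20 + k
        up = _human_sequence(alignments, rec.chrom, lo, hi)
        if rec.strand == "-" and up:
            up = up.translate(_COMPLEMENT)[::-1]
        tata.append(scan_tata(up, p_threshold=tata_threshold)
                    if up and len(up) >= k else False)
    out["gc_count"] = gc
    out["tata"] = tata
    out["cpg_overlap"] = (annotate_overlaps(out, cpg_islands)
                          if cpg_islands is not None else False)
    out["repeat_overlap"] = (annotate_overlaps(out, repeats)
                             if repeats is not None else False)
    if gene_models is not None:
        out = assign_isoform_count(out, gene_models)
    return out


def _human_sequence(alignments: AlignmentIndex, chrom: str, start: int,
                    end: int) -> str:
    """Ungapped human sequence for [start, end) from one covering block."""
    for b in alignments.covering(chrom, start):
        if b.ref_end >= end and "human" in b.rows:
            text = b.rows["human"].text.replace("-", "")
            off = start - b.ref_start
            return text[off: off + (end - start)]
    return ""
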