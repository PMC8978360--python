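"""Between-individual expression variability by promoter architecture.

Per gene, the coefficient of variation CV = sd / mean is computed across
samples for genes expressed (value > 0) in at least 10 samples. Genes are
grouped by the evolutionary architecture of their promoters — conserved-only
as the reference, and for each volatile class a stratum with and without a
co-occurring conserved promoter — and group CV distributions are compared
with two-sided Mann-Whitney tests under Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_EXPRESSED_SAMPLES = 10
VOLATILE_CLASSES = ("functional_turnover", "human_inserted", "mouse_deleted")


@dataclass
class CVRecord:
    gene_id: str
    n_expressed_samples: int
    mean: float
    sd: float
    cv: float


@dataclass
class GeneArchitecture:
    """Promoter-class composition of one gene."""

    gene_id: str
    has_conserved: bool
    volatile_classes: tuple[str, ...]

    @property
    def groups(self) -> tuple[str, ...]:
        """Group labels the gene contributes to.

        ``conserved_only`` for genes with only conserved promoters; else one
        ``<class>:+conserved`` / ``<class>:-conserved`` label per volatile
        class present (a gene with k volatile classes joins k groups).
        """
        if not self.volatile_classes:
            return ("conserved_only",) if self.has_conserved else ()
        tag = "+conserved" if self.has_conserved else "-conserved"
        return tuple(f"{c}:{tag}" for c in self.volatile_classes)


def coefficient_of_variation(values, gene_id: str = "",
                             use_expressed_only: bool = False) -> CVRecord | None:
    """CV of one gene's expression vector, or None when excluded.

    Excluded when fewer than 10 samples have value > 0. By default the mean
    and sample (n-1) standard deviation are taken over all samples once the
    filter passes; ``use_expressed_only`` restricts both to expressed
    samples instead.
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("expression values must be >= 0")
    expressed = v > 0
    n_expr = int(expressed.sum())
    if n_expr < MIN_EXPRESSED_SAMPLES:
        return None
    use = v[expressed] if use_expressed_only else v
    mean = float(use.mean())
    if mean == 0:
        return None  # unreachable with >=10 expressed samples; guarded anyway
    sd = float(use.std(ddof=1))
    return CVRecord(gene_id=gene_id, n_expressed_samples=n_expr, mean=mean,
                    sd=sd, cv=sd / mean)


def cv_table(expression: pd.DataFrame,
             use_expressed_only: bool = False) -> pd.DataFrame:
    """Per-gene CV records for a genes x samples matrix (gene_id column)."""
    sample_cols = [c for c in expression.columns if c != "gene_id"]
    rows = []
    for gid, vals in zip(expression["gene_id"],
                         expression[sample_cols].to_numpy(dtype=float)):
        r = coefficient_of_variation(vals, gene_id=gid,
                                     use_expressed_only=use_expressed_only)
        if r is not None:
            rows.append(vars(r))
    if not rows:
        return pd.DataFrame(columns=["gene_id", "n_expressed_samples", "mean",
                                     "sd", "cv"])
    return pd.DataFrame(rows)


def classify_gene_architecture(gene_id: str,
                               promoters: pd.DataFrame) -> GeneArchitecture | None:
    """Architecture of one gene from its classified promoters."""
    sub = promoters[(promoters["gene_id"] == gene_id)
                    & (promoters["history"] != "unclassified")]
    if len(sub) == 0:
        logger.info("gene %s has no classified promoters", gene_id)
        return None
    labels = set(sub["history"])
    return GeneArchitecture(
        gene_id=gene_id,
        has_conserved="conserved" in labels,
        volatile_classes=tuple(c for c in VOLATILE_CLASSES if c in labels),
    )


def architecture_groups(promoters: pd.DataFrame) -> pd.DataFrame:
    """Long table of (gene_id, group) memberships over all genes."""
    rows = []
    for gid in promoters["gene_id"].dropna().unique():
        arch = classify_gene_architecture(gid, promoters)
        if arch is None:
            continue
        for g in arch.groups:
            rows.append({"gene_id": gid, "group": g})
    return pd.DataFrame(rows, columns=["gene_id", "group"])


def compare_cv(groups: dict[str, np.ndarray],
               n_tests: int | None = None) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of CV distributions.

    Each volatile group is tested against ``conserved_only``, and the
    +/-conserved strata within each volatile class against each other.
    Bonferroni correction uses `n_tests` (default: the number of
    comparisons emitted), capped at 1.
    """
    pairs = []
    for label in sorted(groups):
        if label == "conserved_only":
            continue
        pairs.append((label, "conserved_only"))
    seen_classes = sorted({label.split(":")[0] for label in groups
                           if ":" in label})
    for cls in seen_classes:
        a, b = f"{cls}:-conserved", f"{cls}:+conserved"
        if a in groups and b in groups:
            pairs.append((a, b))
    pairs = [(a, b) for a, b in pairs if a in groups and b in groups]
    valid = []
    for a, b in pairs:
        if len(groups[a]) == 0 or len(groups[b]) == 0:
            logger.warning("comparison %s vs %s skipped: empty group", a, b)
            continue
        valid.append((a, b))
    if n_tests is None:
        n_tests = len(valid)
    rows = []
    for a, b in valid:
        stat, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "n_a": len(groups[a]),
                     "n_b": len(groups[b]),
                     "median_a": float(np.median(groups[a])),
                     "median_b": float(np.median(groups[b])),
                     "statistic": float(stat), "p": float(p),
                     "p_corrected": min(float(p) * n_tests, 1.0)})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b",
                                       "median_a", "median_b", "statistic",
                                       "p", "p_corrected"])


def cv_by_architecture(expression: pd.DataFrame, promoters: pd.DataFrame,
                       use_expressed_only: bool = False) -> dict[str, np.ndarray]:
    """Group label -> CV vector, joining the CV table with architectures."""
    cvs = cv_table(expression, use_expressed_only=use_expressed_only)
    memberships = architecture_groups(promoters)
    joined = memberships.merge(cvs[["gene_id", "cv"]], on="gene_id")
    return {g: sub["cv"].to_numpy() for g, sub in joined.groupby("group")}


def median_cv_across_tissues(per_tissue_cv: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-gene median CV over tissue-level CV tables (aggregate analysis)."""
    frames = [df[["gene_id", "cv"]].assign(tissue=t)
              for t, df in per_tissue_cv.items()]
    if not frames:
        return pd.DataFrame(columns=["gene_id", "cv"])
    allcv = pd.concat(frames)
    med = allcv.groupby("gene_id")["cv"].median().reset_index()
    return med
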