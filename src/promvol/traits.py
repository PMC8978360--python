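"""Trait-variant overlap by promoter class and the covariate regression.

Per-category percentages of promoters overlapping phenotype-associated
variant tracks are reported with bootstrap confidence intervals, against
two baselines: genome-wide permuted promoter positions and the all-variant
track. The multivariate enrichment model is a binomial-family GLM with
logit link,

    overlap ~ history + gc_count + cpg + tata + repeat + isoform_count

with the conserved class as the reference level; coefficients with p > 0.05
are reported as zero alongside the raw fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exact import conditional_mle_odds_ratio
from .intervals import intervals_overlap_any, merge_intervals

logger = logging.getLogger(__name__)

N_BOOT_OVERLAP = 1_000
REGRESSION_TERMS = ("gc_count", "cpg_overlap", "tata", "repeat_overlap",
                    "isoform_count")
STRUCTURAL_MARKERS = ("cnv", "deldup", "clinvar", "insertion", "deletion", "indel")


@dataclass
class RegressionResult:
    """GLM fit of promoter covariates against a binary overlap response."""

    response: str
    coefficients: dict          # term -> (beta, p)
    zeroed: dict                # term -> beta after the p > 0.05 -> 0 rule
    baseline: str = "conserved promoters"
    unestimable: tuple = ()
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": t, "beta": b, "p": p, "beta_zeroed": self.zeroed[t]}
                for t, (b, p) in self.coefficients.items()]
        return pd.DataFrame(rows)


@dataclass
class OverlapSummary:
    """Percent of a category's promoters overlapping a variant track."""

    category: str
    percent: float
    ci_low: float
    ci_high: float
    n_promoters: int
    permuted_ci: tuple[float, float] | None = None
    all_variant_ci: tuple[float, float] | None = None


def fit_covariate_model(promoter_table: pd.DataFrame, response,
                        alpha: float = 0.05,
                        response_label: str = "variant") -> RegressionResult:
    """Binomial/logit GLM of a binary per-promoter response on history and
    sequence/gene covariates, conserved history as reference level."""
    y = np.asarray(response, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("response must contain both classes (0 and 1)")
    df = promoter_table.copy()
    hist = pd.Categorical(
        df["history"],
        categories=["conserved", "functional_turnover", "human_inserted",
                    "mouse_deleted"],
    )
    X = pd.get_dummies(pd.DataFrame({"history": hist}), drop_first=True,
                       dtype=float)
    for term in REGRESSION_TERMS:
        if term in df.columns:
            X[term] = np.asarray(df[term], dtype=float)
    X = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    unestimable = []
    try:
        fit = model.fit()
        converged = bool(getattr(fit, "converged", True))
    except Exception as e:  # complete separation and friends
        logger.warning("GLM failed (%s); refitting with regularization for "
                       "diagnosis", e)
        fit = model.fit_regularized(alpha=1e-6, L1_wt=0.0)
        converged = False
    params = pd.Series(fit.params, index=X.columns)
    try:
        pvals = pd.Series(fit.pvalues, index=X.columns)
    except Exception:
        pvals = pd.Series(np.nan, index=X.columns)
    # flag exploding coefficients as unestimable rather than reporting them
    coefficients, zeroed = {}, {}
    for term in X.columns:
        b, p = float(params[term]), float(pvals[term])
        if abs(b) > 15 or not np.isfinite(p):
            unestimable.append(term)
            coefficients[term] = (np.nan, np.nan)
            zeroed[term] = 0.0
            continue
        coefficients[term] = (b, p)
        zeroed[term] = b if p <= alpha else 0.0
    return RegressionResult(response=response_label, coefficients=coefficients,
                            zeroed=zeroed, unestimable=tuple(unestimable),
                            converged=converged)


def permuted_baseline(promoters: pd.DataFrame, genome_length: int,
                      n_perm: int, seed: int = 0) -> list[pd.DataFrame]:
    """Length-preserving uniform random placements of the promoter set.

    Each permutation keeps the length multiset and draws starts uniformly
    on the single synthetic chromosome (no exclusion zones).
    """
    lengths = (promoters["end"] - promoters["start"]).to_numpy(dtype=np.int64)
    if len(lengths) and genome_length <= int(lengths.max()):
        raise ValueError("genome_length must exceed the longest promoter")
    rng = np.random.default_rng(seed)
    chrom = promoters["chrom"].iloc[0] if len(promoters) else "chr1"
    perms = []
    for _ in range(n_perm):
        starts = rng.integers(0, genome_length - lengths, endpoint=False)
        perms.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                   "end": starts + lengths}))
    return perms


def _overlap_flags(intervals: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    flags = np.zeros(len(intervals), dtype=bool)
    merged = {c: merge_intervals(s["start"].to_numpy(), s["end"].to_numpy())
              for c, s in track.groupby("chrom")}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        idx = intervals.index.get_indexer(sub.index)
        if chrom in merged:
            flags[idx] = intervals_overlap_any(sub["start"].to_numpy(),
                                               sub["end"].to_numpy(),
                                               *merged[chrom])
    return flags


def _boot_percent_ci(flags: np.ndarray, n_boot: int,
                     rng: np.random.Generator) -> tuple[float, float]:
    n = flags.size
    draws = rng.integers(0, n, size=(n_boot, n))
    pct = flags[draws].mean(axis=1) * 100.0
    lo, hi = np.percentile(pct, [2.5, 97.5])
    return float(lo), float(hi)


def overlap_phenotype_variants(promoters: pd.DataFrame, track: pd.DataFrame, *,
                               n_boot: int = N_BOOT_OVERLAP, seed: int = 0,
                               genome_length: int | None = None,
                               n_perm: int = 1_000,
                               all_variant_track: pd.DataFrame | None = None,
                               ) -> list[OverlapSummary]:
    """Per-category percent of promoters overlapping a merged variant track.

    Bootstrap CIs resample promoters (1000 draws); optional baseline bands
    come from genome-permuted promoter positions and from the all-variant
    track overlap of the same promoters.
    """
    rng = np.random.default_rng(seed)
    flags_all = _overlap_flags(promoters, track)
    permuted_ci = None
    if genome_length is not None and n_perm > 0:
        perm_pcts = []
        for perm in permuted_baseline(promoters, genome_length, n_perm, seed=seed):
            perm_pcts.append(_overlap_flags(perm, track).mean() * 100.0)
        permuted_ci = tuple(np.percentile(perm_pcts, [2.5, 97.5]))
    out = []
    for cat, sub in promoters.groupby("history", sort=True):
        if cat == "unclassified" or len(sub) == 0:
            continue
        flags = flags_all[promoters.index.get_indexer(sub.index)]
        pct = float(flags.mean() * 100.0)
        if n_boot > 0:
            lo, hi = _boot_percent_ci(flags, n_boot, rng)
        else:
            lo = hi = pct
        av_ci = None
        if all_variant_track is not None:
            av_flags = _overlap_flags(sub.reset_index(drop=True), all_variant_track)
            av_ci = _boot_percent_ci(av_flags, max(n_boot, 1), rng)
        out.append(OverlapSummary(category=cat, percent=pct, ci_low=lo,
                                  ci_high=hi, n_promoters=len(sub),
                                  permuted_ci=permuted_ci, all_variant_ci=av_ci))
    return out


def classify_variant_tracks(track_metadata: pd.DataFrame) -> pd.DataFrame:
    """Label tracks as sequence or structural variant collections.

    Structural when the track name or description contains (case-insensitive)
    a CNV/DelDup/ClinVar/indel marker; sequence otherwise.
    """
    text = (track_metadata.get("track", pd.Series("", index=track_metadata.index))
            .astype(str)
            + " "
            + track_metadata.get("description",
                                 pd.Series("", index=track_metadata.index)).astype(str)
            ).str.lower()
    is_structural = text.apply(lambda t: any(m in t for m in STRUCTURAL_MARKERS))
    out = track_metadata.copy()
    out["variant_class"] = np.where(is_structural, "structural", "sequence")
    return out


def region_overlap_or(promoters_by_category: dict[str, pd.DataFrame],
                      regions: pd.DataFrame,
                      permuted: list[pd.DataFrame],
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-category log2 OR of overlap with candidate regions vs permutation.

    Fisher's exact test on overlapping/non-overlapping counts against the
    pooled permuted placements; Bonferroni-corrected across categories.
    """
    if len(regions) == 0:
        raise ValueError("no candidate regions supplied")
    if not permuted:
        raise ValueError("permuted baseline required")
    perm_all = pd.concat(permuted, ignore_index=True)
    perm_flags = _overlap_flags(perm_all, regions)
    base_with, base_without = int(perm_flags.sum()), int((~perm_flags).sum())
    n_tests = len(promoters_by_category)
    rows = []
    for cat, sub in sorted(promoters_by_category.items()):
        flags = _overlap_flags(sub.reset_index(drop=True), regions)
        w, wo = int(flags.sum()), int((~flags).sum())
        table = np.array([[w, wo], [base_with, base_without]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            rows.append({"category": cat, "with": w, "without": wo,
                         "log2_or": np.nan, "p": 1.0, "p_corrected": 1.0})
            continue
        _, p = stats.fisher_exact(table)
        or_hat = conditional_mle_odds_ratio(table)
        with np.errstate(divide="ignore"):
            rows.append({"category": cat, "with": w, "without": wo,
                         "log2_or": float(np.log2(or_hat)),
                         "p": float(p),
                         "p_corrected": min(float(p) * n_tests, 1.0)})
    return pd.DataFrame(rows, columns=["category", "with", "without", "log2_or",
                                       "p", "p_corrected"])
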