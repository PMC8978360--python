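"""Spatial polymorphism metaprofiles and derived-allele-frequency selection tests.

The enrichment profile is the 250 bp rolling average of per-anchor event
rates at each offset from the promoter anchor (TSS by default, midpoint
optional; minus-strand promoters are orientation-flipped), normalized to
the mean rate over the 2-4 kb flanks, with percentile confidence bands from
bootstrap resampling of promoters.

The DAF test compares rare (< 1.5%) to common (> 5%) derived-allele counts
between promoter regions (cluster span +/- 50 bp) and the 2-4 kb
neutral-proxy flank with Fisher's exact test. log2(odds ratio) > 0 indicates
purifying selection, < 0 diversifying selection. The point estimate is the
conditional-MLE odds ratio with exact confidence bounds; the level is
Bonferroni-adjusted for the test family size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exact import conditional_mle_odds_ratio, exact_odds_ratio_ci
from .intervals import merge_intervals, positions_in_intervals

logger = logging.getLogger(__name__)

ROLLING_WINDOW = 250          # bp
NEUTRAL_FLANK = (2_000, 4_000)  # bp from the anchor
PROMOTER_HALO = 50            # bp each side of the cluster span
N_BOOT_PROFILE = 100


@dataclass
class EnrichmentProfile:
    """Position-indexed normalized event-rate curve with bootstrap bands."""

    offsets: np.ndarray
    rate: np.ndarray
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    n_anchors: int
    n_events: int
    normalizer: float        # mean raw rate over the flank region

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.offsets, "rate": self.rate})
        if self.ci_low is not None:
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
        return df


@dataclass
class DAFTestResult:
    """Fisher's exact rare-vs-common comparison of promoter against flank."""

    rare_prom: int
    common_prom: int
    rare_flank: int
    common_flank: int
    log2_or: float
    p: float
    ci_low: float
    ci_high: float
    n_tests: int = 1
    sample_log2_or: float = np.nan   # cross-product estimate
    degenerate: bool = False
    label: dict = field(default_factory=dict)

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.rare_prom, self.common_prom],
                         [self.rare_flank, self.common_flank]])


def _anchor_positions(promoters: pd.DataFrame, anchor: str) -> np.ndarray:
    if anchor == "midpoint":
        return ((promoters["start"].to_numpy() + promoters["end"].to_numpy()) // 2)
    if "tss" in promoters.columns:
        return promoters["tss"].to_numpy(dtype=np.int64)
    return ((promoters["start"].to_numpy() + promoters["end"].to_numpy()) // 2)


def spatial_enrichment(events: np.ndarray, anchors: pd.DataFrame, *,
                       window: int = ROLLING_WINDOW, span: int = 4_000,
                       flank: tuple[int, int] = NEUTRAL_FLANK,
                       n_boot: int = N_BOOT_PROFILE, seed: int = 0,
                       anchor: str = "tss",
                       flank_side: str = "both") -> EnrichmentProfile:
    """Normalized rolling event-rate profile around promoter anchors.

    `events` are genomic positions (0-based) on the anchors' chromosome
    coordinate system; orientation follows each promoter's strand. The rate
    at each offset is the mean per-bp event rate in a centered `window`
    rolling average (truncated at the span edges), divided by the mean rate
    over the flank region on the requested side(s).
    """
    if span < flank[1]:
        raise ValueError("span must cover the flank region")
    if len(anchors) == 0:
        raise ValueError("no anchors supplied")
    events = np.asarray(events, dtype=np.int64)
    pos = _anchor_positions(anchors, anchor)
    strands = (anchors["strand"].to_numpy() if "strand" in anchors.columns
               else np.full(len(anchors), "+"))

    lo, hi = -span, span
    width = hi - lo + 1
    counts = np.zeros((len(anchors), width), dtype=np.float64)
    n_events = 0
    for i, (a, s) in enumerate(zip(pos, strands)):
        offs = events - a
        if s == "-":
            offs = -offs
        offs = offs[(offs >= lo) & (offs <= hi)]
        n_events += offs.size
        if offs.size:
            counts[i] = np.bincount(offs - lo, minlength=width)

    kernel = np.ones(window)
    offsets = np.arange(lo, hi + 1)
    flank_mask = _flank_mask(offsets, flank, flank_side)

    coverage = np.convolve(np.ones(width), kernel, mode="same")

    def normalized(weights: np.ndarray):
        total = weights @ counts
        smooth = np.convolve(total, kernel, mode="same") / (coverage * weights.sum())
        norm = smooth[flank_mask].mean()
        if norm == 0:
            raise ValueError(
                "enrichment profile undefined: zero events in the "
                f"{flank[0]}-{flank[1]} bp flank normalizer")
        return smooth / norm, norm

    rate, normalizer = normalized(np.ones(len(anchors)))
    ci_low = ci_high = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, width))
        for b in range(n_boot):
            rows = rng.integers(0, len(anchors), size=len(anchors))
            weights = np.bincount(rows, minlength=len(anchors)).astype(float)
            try:
                reps[b], _ = normalized(weights)
            except ValueError:
                reps[b] = np.nan
        ci_low, ci_high = np.nanpercentile(reps, [2.5, 97.5], axis=0)
    return EnrichmentProfile(offsets=offsets, rate=rate, ci_low=ci_low,
                             ci_high=ci_high, n_anchors=len(anchors),
                             n_events=n_events, normalizer=float(normalizer))


def _flank_mask(offsets: np.ndarray, flank: tuple[int, int], side: str) -> np.ndarray:
    a, b = flank
    up = (offsets <= -a) & (offsets >= -b)
    down = (offsets >= a) & (offsets <= b)
    if side == "upstream":
        return up
    if side == "downstream":
        return down
    return up | down


def collect_region_counts(polarized: pd.DataFrame, promoters: pd.DataFrame, *,
                          promoter_halo: int = PROMOTER_HALO,
                          neutral_flank: tuple[int, int] = NEUTRAL_FLANK,
                          flank_side: str = "upstream",
                          population: str = "all") -> tuple[int, int, int, int]:
    """Rare/common counts in merged promoter-halo and neutral-flank regions.

    Intermediate-frequency variants contribute to neither cell. Overlapping
    halos are merged so no variant is double counted.
    """
    cls_col = f"daf_class_{population.lower()}"
    df = polarized[polarized["resolution"].isin(["retained", "reversed"])]
    if len(df) == 0 or len(promoters) == 0:
        return (0, 0, 0, 0)
    prom_regions, flank_regions = region_intervals(
        promoters, promoter_halo=promoter_halo, neutral_flank=neutral_flank,
        flank_side=flank_side)
    rare = common = rare_f = common_f = 0
    for chrom, sub in df.groupby("chrom"):
        pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1
        klass = sub[cls_col].to_numpy()
        in_prom = (positions_in_intervals(pos0, *prom_regions[chrom])
                   if chrom in prom_regions else np.zeros(pos0.size, bool))
        in_flank = (positions_in_intervals(pos0, *flank_regions[chrom])
                    if chrom in flank_regions else np.zeros(pos0.size, bool))
        in_flank &= ~in_prom  # halo wins where regions touch
        rare += int(((klass == "rare") & in_prom).sum())
        common += int(((klass == "common") & in_prom).sum())
        rare_f += int(((klass == "rare") & in_flank).sum())
        common_f += int(((klass == "common") & in_flank).sum())
    return rare, common, rare_f, common_f


def region_intervals(promoters: pd.DataFrame, *, promoter_halo: int,
                     neutral_flank: tuple[int, int],
                     flank_side: str = "upstream"):
    """Merged promoter-halo and neutral-flank interval sets per chromosome."""
    prom, flank = {}, {}
    a, b = neutral_flank
    for chrom, sub in promoters.groupby("chrom"):
        starts = sub["start"].to_numpy(dtype=np.int64) - promoter_halo
        ends = sub["end"].to_numpy(dtype=np.int64) + promoter_halo
        prom[chrom] = merge_intervals(starts, ends)
        tss = _anchor_positions(sub, "tss")
        strand = (sub["strand"].to_numpy() if "strand" in sub.columns
                  else np.full(len(sub), "+"))
        fs, fe = [], []
        for t, s in zip(tss, strand):
            upstream = (t - b, t - a) if s != "-" else (t + a, t + b)
            downstream = (t + a, t + b) if s != "-" else (t - b, t - a)
            if flank_side in ("upstream", "both"):
                fs.append(upstream[0]); fe.append(upstream[1])
            if flank_side in ("downstream", "both"):
                fs.append(downstream[0]); fe.append(downstream[1])
        flank[chrom] = merge_intervals(np.array(fs), np.array(fe))
    return prom, flank


def daf_test(counts: tuple[int, int, int, int], alpha: float = 0.05,
             n_tests: int = 1, label: dict | None = None) -> DAFTestResult:
    """Two-sided Fisher's exact test on the rare/common x promoter/flank table.

    The reported odds ratio is the conditional maximum-likelihood estimate
    with an exact confidence interval at level 1 - alpha/n_tests; the
    cross-product sample odds ratio is carried alongside.
    """
    rare_p, common_p, rare_f, common_f = (int(c) for c in counts)
    if min(rare_p, common_p, rare_f, common_f) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[rare_p, common_p], [rare_f, common_f]])
    label = label or {}
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return DAFTestResult(rare_p, common_p, rare_f, common_f,
                             log2_or=np.nan, p=1.0, ci_low=np.nan,
                             ci_high=np.nan, n_tests=n_tests, degenerate=True,
                             label=label)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    level = 1.0 - alpha / n_tests
    or_hat = conditional_mle_odds_ratio(table)
    lo, hi = exact_odds_ratio_ci(table, confidence_level=level)
    with np.errstate(divide="ignore"):
        sample = ((rare_p * common_f) / (common_p * rare_f)
                  if common_p * rare_f > 0 else np.inf)
        return DAFTestResult(rare_p, common_p, rare_f, common_f,
                             log2_or=float(np.log2(or_hat)), p=float(p),
                             ci_low=float(np.log2(lo)),
                             ci_high=float(np.log2(hi)),
                             n_tests=n_tests,
                             sample_log2_or=float(np.log2(sample)),
                             label=label)


def bonferroni_confidence_level(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Per-test confidence level (%) giving family-wise 1 - alpha coverage."""
    return (1.0 - alpha / n_tests) * 100.0


def downsample_categories(promoters: pd.DataFrame, n: int,
                          seed: int = 0) -> pd.DataFrame:
    """Uniformly downsample each history category to at most `n` promoters."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    parts = []
    for hist, sub in promoters.groupby("history", sort=True):
        if len(sub) <= n:
            if len(sub) < n:
                logger.warning("category %s has only %d promoters (< %d): kept all",
                               hist, len(sub), n)
            parts.append(sub)
        else:
            take = rng.choice(len(sub), size=n, replace=False)
            parts.append(sub.iloc[np.sort(take)])
    return pd.concat(parts).sort_index().reset_index(drop=True)


def per_population_daf(polarized: pd.DataFrame, promoters: pd.DataFrame,
                       populations=("AFR", "AMR", "EAS", "EUR", "SAS"), *,
                       categories: list[str] | None = None,
                       vclasses=("SNP", "insertion", "deletion"),
                       alpha: float = 0.05,
                       promoter_halo: int = PROMOTER_HALO,
                       neutral_flank: tuple[int, int] = NEUTRAL_FLANK,
                       flank_side: str = "upstream") -> list[DAFTestResult]:
    """One DAF test per (population, history category, variant class).

    The Bonferroni family size is the number of tests emitted by this
    invocation.
    """
    if categories is None:
        categories = sorted(promoters["history"].unique())
        categories = [c for c in categories if c != "unclassified"]
    jobs = []
    for pop in populations:
        col = f"daf_class_{pop.lower()}"
        if col not in polarized.columns or polarized[col].eq("").all():
            logger.warning("population %s absent from polarized variants: skipped", pop)
            continue
        for cat in categories:
            sub_prom = promoters[promoters["history"] == cat]
            if len(sub_prom) == 0:
                continue
            for vc in vclasses:
                sub_var = polarized[polarized["vclass"] == vc]
                jobs.append((pop, cat, vc, sub_prom, sub_var))
    n_tests = len(jobs)
    results = []
    for pop, cat, vc, sub_prom, sub_var in jobs:
        counts = collect_region_counts(sub_var, sub_prom, population=pop,
                                       promoter_halo=promoter_halo,
                                       neutral_flank=neutral_flank,
                                       flank_side=flank_side)
        results.append(daf_test(counts, alpha=alpha, n_tests=n_tests,
                                label={"population": pop, "category": cat,
                                       "vclass": vc}))
    return results


def daf_results_to_frame(results: list[DAFTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dict(r.label)
        row.update(rare_prom=r.rare_prom, common_prom=r.common_prom,
                   rare_flank=r.rare_flank, common_flank=r.common_flank,
                   log2_or=r.log2_or, sample_log2_or=r.sample_log2_or,
                   p=r.p, ci_low=r.ci_low, ci_high=r.ci_high,
                   n_tests=r.n_tests, degenerate=r.degenerate)
        rows.append(row)
    return pd.DataFrame(rows)
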