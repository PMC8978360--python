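"""Molecular/expression QTL association with promoters and enrichment tests.

QTLs are associated to every promoter whose TSS lies within 50 bp
(inclusive); an association is significant when |beta| > SE. Per-category
overlap enrichment is a Fisher's exact test against the conserved class
(or a shuffled-genome baseline). Effect sizes are re-signed to the derived
allele (``derived_beta``): positive means the derived allele increases the
phenotype. The tissue-consensus test asks whether the observed split of
tissues with median derived beta below zero deviates from the 50:50 null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exact import conditional_mle_odds_ratio, exact_odds_ratio_ci

logger = logging.getLogger(__name__)

QTL_MAX_DIST = 50   # bp from the promoter TSS, inclusive


@dataclass
class OverlapOddsResult:
    """2x2 promoter-overlap enrichment of one category against a baseline."""

    category: str
    with_qtl: int
    without_qtl: int
    baseline_with: int
    baseline_without: int
    log2_or: float
    p: float
    ci_low: float
    ci_high: float
    baseline: str = "conserved"


def significant_molecular_qtl(beta: float, se: float) -> bool:
    """Significance rule for molecular QTL: |beta| strictly exceeds its SE."""
    if se < 0:
        raise ValueError("standard error must be >= 0")
    return abs(beta) > se


def associate_qtl(qtls: pd.DataFrame, promoters: pd.DataFrame,
                  max_dist: int = QTL_MAX_DIST) -> pd.DataFrame:
    """Map QTL records to promoters within `max_dist` bp of the TSS.

    Returns the QTL table replicated per associated promoter with
    ``promoter_id``, ``history`` and ``distance`` columns; a QTL within
    range of several promoters maps to all of them.
    """
    out = []
    tss = (promoters["tss"] if "tss" in promoters.columns
           else (promoters["start"] + promoters["end"]) // 2)
    for chrom, prom_sub in promoters.assign(_tss=tss).groupby("chrom"):
        q_sub = qtls[qtls["chrom"] == chrom]
        if len(q_sub) == 0:
            continue
        order = np.argsort(prom_sub["_tss"].to_numpy())
        ptss = prom_sub["_tss"].to_numpy()[order]
        pids = prom_sub["id"].to_numpy()[order]
        hist = (prom_sub["history"].to_numpy()[order]
                if "history" in prom_sub.columns else np.full(len(prom_sub), ""))
        qpos = q_sub["pos"].to_numpy(dtype=np.int64) - 1
        lo = np.searchsorted(ptss, qpos - max_dist, side="left")
        hi = np.searchsorted(ptss, qpos + max_dist, side="right")
        for k, (_, row) in enumerate(q_sub.iterrows()):
            for j in range(lo[k], hi[k]):
                rec = row.to_dict()
                rec["promoter_id"] = pids[j]
                rec["history"] = hist[j]
                rec["distance"] = int(abs(qpos[k] - ptss[j]))
                out.append(rec)
    if not out:
        return pd.DataFrame(columns=list(qtls.columns) + ["promoter_id", "history",
                                                          "distance"])
    return pd.DataFrame(out)


def overlap_odds(promoters: pd.DataFrame, qtl_flags: pd.Series | np.ndarray, *,
                 baseline: str = "conserved",
                 baseline_flags: np.ndarray | None = None,
                 alpha: float = 0.05) -> list[OverlapOddsResult]:
    """Per-category QTL-overlap enrichment against the baseline class.

    `qtl_flags` is a boolean per promoter (>= 1 associated QTL). With
    ``baseline="shuffled"``, supply `baseline_flags` computed on permuted
    promoter positions (see :func:`promvol.traits.permuted_baseline`).
    """
    flags = np.asarray(qtl_flags, dtype=bool)
    results = []
    if baseline == "conserved":
        base_mask = promoters["history"].eq("conserved").to_numpy()
        base_with = int(flags[base_mask].sum())
        base_without = int((~flags[base_mask]).sum())
    else:
        if baseline_flags is None:
            raise ValueError("shuffled baseline requires baseline_flags")
        base_with = int(np.asarray(baseline_flags).sum())
        base_without = int((~np.asarray(baseline_flags, dtype=bool)).sum())
    categories = [c for c in sorted(promoters["history"].unique())
                  if c not in ("unclassified",)
                  and not (baseline == "conserved" and c == "conserved")]
    for cat in categories:
        mask = promoters["history"].eq(cat).to_numpy()
        if mask.sum() == 0:
            logger.warning("category %s empty: skipped", cat)
            continue
        w, wo = int(flags[mask].sum()), int((~flags[mask]).sum())
        table = np.array([[w, wo], [base_with, base_without]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            results.append(OverlapOddsResult(cat, w, wo, base_with, base_without,
                                             np.nan, 1.0, np.nan, np.nan, baseline))
            continue
        _, p = stats.fisher_exact(table)
        or_hat = conditional_mle_odds_ratio(table)
        lo, hi = exact_odds_ratio_ci(table, confidence_level=1 - alpha)
        with np.errstate(divide="ignore"):
            results.append(OverlapOddsResult(
                cat, w, wo, base_with, base_without,
                float(np.log2(or_hat)), float(p),
                float(np.log2(lo)), float(np.log2(hi)), baseline))
    return results


def derive_beta(beta: float, resolution: str) -> float | None:
    """Re-sign an alt-allele effect to the ancestral -> derived direction."""
    if resolution == "retained":
        return float(beta)
    if resolution == "reversed":
        return -float(beta)
    return None


def attach_derived_beta(qtls: pd.DataFrame,
                        polarized: pd.DataFrame) -> pd.DataFrame:
    """Join QTL records with polarized variants and add ``derived_beta``."""
    pol = polarized.set_index(["chrom", "pos"])[["resolution"]]
    out = qtls.join(pol, on=["chrom", "pos"])
    out["resolution"] = out["resolution"].fillna("excluded")
    out["derived_beta"] = [
        derive_beta(b, r) if r in ("retained", "reversed") else np.nan
        for b, r in zip(out["beta"], out["resolution"])
    ]
    return out


def tissue_consensus(per_tissue_median: dict[str, float] | pd.Series,
                     ) -> tuple[int, int, float]:
    """Exact test of the across-tissue direction consensus against 50:50.

    `per_tissue_median` maps tissue -> median derived beta. Tissues with a
    median of exactly zero are dropped (logged). Returns (n_reduced,
    n_total, p) where p comes from Fisher's exact test of the observed
    (reduced, increased) split against an expected 50:50 split of the same
    total.
    """
    med = pd.Series(per_tissue_median, dtype=float)
    zeros = med.eq(0.0)
    if zeros.any():
        logger.info("dropping %d tissues with median derived beta exactly 0",
                    int(zeros.sum()))
        med = med[~zeros]
    if len(med) == 0:
        raise ValueError("tissue consensus undefined: all medians are zero")
    n_total = len(med)
    n_reduced = int((med < 0).sum())
    expected = n_total // 2
    table = np.array([[n_reduced, n_total - n_reduced],
                      [expected, n_total - expected]])
    _, p = stats.fisher_exact(table)
    return n_reduced, n_total, float(p)


def compare_beta_distributions(group_a, group_b,
                               n_tests: int = 1) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney comparison of two derived-beta samples.

    Returns (U statistic, p, Bonferroni-corrected p capped at 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    # exact null distribution at small n (no ties); asymptotic otherwise
    method = ("exact" if min(a.size, b.size) <= 25
              and np.unique(pooled).size == pooled.size else "asymptotic")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(stat), float(p), min(float(p) * n_tests, 1.0)
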