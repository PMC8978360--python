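"""Ancestral-state resolution and derived-allele frequencies.

For every variant the reference position +/- 2 bp is projected through the
alignment and the closest available ancestral sequence recorded. SNPs are
resolved by the ancestral base at the variant column: equal to REF ->
*retained* (ALT is derived), equal to ALT -> *reversed* (REF is derived),
anything else, a gapped window or no alignment -> *excluded*. Indels are
resolved by comparing the gap-stripped length of the ancestral window to
the window lengths implied by the REF and ALT alleles — never by sequence
identity — with the annotated insertion/deletion type swapped when the
ancestral length matches the ALT allele.

Derived allele frequency (DAF) is then 1 minus the ancestral-allele
frequency, computed for the combined panel and each super-population, and
binned as rare (< 1.5%), common (> 5%) or intermediate.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AlignmentIndex, GAP

logger = logging.getLogger(__name__)

RARE_MAX_DAF = 0.015    # rare: daf < 1.5%
COMMON_MIN_DAF = 0.05   # common: daf > 5%
WINDOW_HALF_WIDTH = 2   # bp each side of the variant span

POPULATIONS = ("ALL", "AFR", "AMR", "EAS", "EUR", "SAS")

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

#: order in which exclusion rules are applied; one reason per record
EXCLUSION_ORDER = ("multi_mapping", "multi_allelic", "unaligned",
                   "gapped_window", "unresolvable")


@dataclass
class AncestralWindow:
    """Aligned ancestral sequence over a human window (variant span +/- 2 bp)."""

    human_seq: str            # human row, gapped as aligned
    ancestral_seq: str        # ancestral row, gapped as aligned
    has_gap_in_window: bool   # any gap in either row over the window
    source: str               # species/node label the ancestral row came from
    variant_column: int       # column of the variant's anchor position


@dataclass
class PolarizedVariant:
    """A variant with resolved ancestral state and derived allele frequency."""

    chrom: str
    pos: int                  # 1-based VCF position
    ref: str
    alt: str
    vclass: str               # SNP | insertion | deletion
    resolution: str           # retained | reversed | excluded
    ancestral_allele: str | None = None
    daf: dict = field(default_factory=dict)        # population -> frequency
    daf_class: dict = field(default_factory=dict)  # population -> class
    transversion: bool | None = None
    exclusion_reason: str | None = None
    ancestral_source: str | None = None
    id: str = "."


def variant_class(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNP"
    return "insertion" if len(alt) > len(ref) else "deletion"


def is_transversion(ref: str, alt: str) -> bool:
    """True iff the substitution swaps a purine for a pyrimidine."""
    r, a = ref.upper(), alt.upper()
    if r not in "ACGT" or a not in "ACGT" or len(r) != 1 or len(a) != 1:
        raise ValueError(f"is_transversion expects single ACGT bases, got {ref!r}->{alt!r}")
    return (r in PURINES) != (a in PURINES)


def classify_daf(daf: float) -> str:
    """Rare (< 1.5%), common (> 5%) or intermediate derived allele frequency."""
    if not 0.0 <= daf <= 1.0:
        raise ValueError(f"derived allele frequency outside [0, 1]: {daf}")
    if daf < RARE_MAX_DAF:
        return "rare"
    if daf > COMMON_MIN_DAF:
        return "common"
    return "intermediate"


def project_window(chrom: str, pos: int, ref: str,
                   alignments: AlignmentIndex) -> AncestralWindow | None:
    """Project the variant span +/- 2 bp through the alignment.

    Among covering blocks, the one with the most closely related ancestral
    row wins (an explicit 'ancestral' row beats any outgroup). Returns None
    when the window is not fully covered by any suitable block.
    """
    pos0 = pos - 1
    lo = pos0 - WINDOW_HALF_WIDTH
    hi = pos0 + len(ref) - 1 + WINDOW_HALF_WIDTH
    if chrom not in alignments.chromosomes:
        logger.warning("variant at %s:%d: chromosome absent from alignments", chrom, pos)
        return None
    from .alignment import ANCESTRAL_PREFERENCE

    candidates = []
    for i, b in enumerate(alignments.covering(chrom, pos0)):
        src = b.ancestral_source()
        if src is None or not (b.ref_start <= lo and hi < b.ref_end):
            continue
        # prefer the closest ancestral source, then the most local block
        # centred on the variant (blocks may overlap)
        width = b.ref_end - b.ref_start
        off_center = abs(2 * (pos0 - b.ref_start) - (width - 1))
        candidates.append((ANCESTRAL_PREFERENCE.index(src), width, off_center,
                           i, src, b))
    if not candidates:
        return None
    candidates.sort(key=lambda t: t[:4])
    _, _, _, _, src, block = candidates[0]
    span = block.window_columns(lo, hi)
    if span is None:
        return None
    c0, c1 = span
    human = block.rows["human"].text[c0: c1 + 1]
    anc = block.rows[src].text[c0: c1 + 1]
    vcol = block.column_of(pos0)
    return AncestralWindow(
        human_seq=human,
        ancestral_seq=anc,
        has_gap_in_window=(GAP in human) or (GAP in anc),
        source=src,
        variant_column=vcol - c0,
    )


def _daf_maps(af_alt: dict[str, float], derived_is_alt: bool):
    daf, daf_class = {}, {}
    for pop, af in af_alt.items():
        if af is None or not np.isfinite(af):
            continue
        d = float(af) if derived_is_alt else 1.0 - float(af)
        daf[pop] = d
        daf_class[pop] = classify_daf(d)
    return daf, daf_class


def resolve_snp(chrom: str, pos: int, ref: str, alt: str,
                window: AncestralWindow | None,
                af_alt: dict[str, float], vid: str = ".") -> PolarizedVariant:
    """Polarize a SNP from the ancestral base at the variant column."""
    base = PolarizedVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, vclass="SNP",
                            resolution="excluded", id=vid,
                            transversion=is_transversion(ref, alt))
    if window is None:
        base.exclusion_reason = "unaligned"
        return base
    base.ancestral_source = window.source
    if window.has_gap_in_window:
        base.exclusion_reason = "gapped_window"
        return base
    anc = window.ancestral_seq[window.variant_column].upper()
    if anc == ref.upper():
        res, derived_is_alt, anc_allele = "retained", True, ref
    elif anc == alt.upper():
        res, derived_is_alt, anc_allele = "reversed", False, alt
    else:
        base.exclusion_reason = "unresolvable"
        return base
    daf, daf_class = _daf_maps(af_alt, derived_is_alt)
    base.resolution = res
    base.ancestral_allele = anc_allele
    base.daf, base.daf_class = daf, daf_class
    return base


def resolve_indel(chrom: str, pos: int, ref: str, alt: str,
                  window: AncestralWindow | None,
                  af_alt: dict[str, float], vid: str = ".") -> PolarizedVariant:
    """Polarize an indel by ancestral window length, not sequence identity."""
    vclass = variant_class(ref, alt)
    base = PolarizedVariant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                            vclass=vclass, resolution="excluded", id=vid)
    if window is None:
        base.exclusion_reason = "unaligned"
        return base
    base.ancestral_source = window.source
    anc_len = len(window.ancestral_seq.replace(GAP, ""))
    # window-equivalent lengths under each allele: the 2 bp flanks plus the
    # allele itself
    len_ref = len(ref) + 2 * WINDOW_HALF_WIDTH
    len_alt = len(alt) + 2 * WINDOW_HALF_WIDTH
    if anc_len == len_ref:
        res, derived_is_alt, anc_allele = "retained", True, ref
    elif anc_len == len_alt:
        # annotated type reverses: the ancestral state matches the ALT allele
        res, derived_is_alt, anc_allele = "reversed", False, alt
    else:
        base.exclusion_reason = "unresolvable"
        return base
    daf, daf_class = _daf_maps(af_alt, derived_is_alt)
    base.resolution = res
    base.ancestral_allele = anc_allele
    base.daf, base.daf_class = daf, daf_class
    return base


def filter_variants(variants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove multi-mapping records and multi-variant positions.

    Returns (kept, exclusion_log); kept + excluded reconcile to the input.
    """
    df = variants.copy()
    reasons = pd.Series("", index=df.index, dtype=object)
    if "id" in df.columns:
        id_counts = df["id"].value_counts()
        multi_map = df["id"].map(id_counts).gt(1) & df["id"].ne(".")
        reasons[multi_map] = "multi_mapping"
    pos_counts = df.groupby(["chrom", "pos"])["pos"].transform("size")
    multi_pos = (pos_counts > 1) & reasons.eq("")
    reasons[multi_pos] = "multi_allelic"
    multi_alt = df["alt"].astype(str).str.contains(",") & reasons.eq("")
    reasons[multi_alt] = "multi_allelic"
    kept = df[reasons.eq("")].reset_index(drop=True)
    log = df[reasons.ne("")].copy()
    log["exclusion_reason"] = reasons[reasons.ne("")]
    return kept, log.reset_index(drop=True)


def polarize_variants(variants: pd.DataFrame,
                      alignments: AlignmentIndex) -> tuple[list[PolarizedVariant], pd.DataFrame]:
    """Filter then polarize a variant table read from VCF.

    Returns the polarized variants (every kept record, including excluded
    resolutions) and the pre-polarization exclusion log.
    """
    kept, log = filter_variants(variants)
    out = []
    for rec in kept.itertuples(index=False):
        af_alt = {"ALL": rec.af}
        for pop in POPULATIONS[1:]:
            af_alt[pop] = getattr(rec, f"af_{pop.lower()}", None)
        window = project_window(rec.chrom, int(rec.pos), rec.ref, alignments)
        if variant_class(rec.ref, rec.alt) == "SNP":
            pv = resolve_snp(rec.chrom, int(rec.pos), rec.ref, rec.alt, window,
                             af_alt, vid=str(rec.id))
        else:
            pv = resolve_indel(rec.chrom, int(rec.pos), rec.ref, rec.alt, window,
                               af_alt, vid=str(rec.id))
        out.append(pv)
    return out, log


def polarized_to_frame(variants: list[PolarizedVariant]) -> pd.DataFrame:
    """Flatten polarized variants to the interchange TSV layout."""
    rows = []
    for v in variants:
        row = {"chrom": v.chrom, "pos": v.pos, "id": v.id, "ref": v.ref,
               "alt": v.alt, "vclass": v.vclass, "resolution": v.resolution,
               "ancestral_allele": v.ancestral_allele or "",
               "ancestral_source": v.ancestral_source or "",
               "exclusion_reason": v.exclusion_reason or "",
               "transversion": v.transversion}
        for pop in POPULATIONS:
            row[f"daf_{pop.lower()}"] = v.daf.get(pop, np.nan)
            row[f"daf_class_{pop.lower()}"] = v.daf_class.get(pop, "")
        rows.append(row)
    cols = (["chrom", "pos", "id", "ref", "alt", "vclass", "resolution",
             "ancestral_allele", "ancestral_source", "exclusion_reason",
             "transversion"]
            + [f"daf_{p.lower()}" for p in POPULATIONS]
            + [f"daf_class_{p.lower()}" for p in POPULATIONS])
    return pd.DataFrame(rows, columns=cols)


def exclusion_tally(variants: list[PolarizedVariant],
                    prefilter_log: pd.DataFrame | None = None) -> Counter:
    """Counts of exclusion reasons across filtering and polarization."""
    tally = Counter()
    if prefilter_log is not None and len(prefilter_log):
        tally.update(prefilter_log["exclusion_reason"].tolist())
    for v in variants:
        if v.resolution == "excluded" and v.exclusion_reason:
            tally[v.exclusion_reason] += 1
    return tally
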