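"""Readers and writers for the pipeline's file formats.

All inter-stage data passes through these functions: BED (0-based half-open)
for intervals, VCF v4.2 for variants (read via cyvcf2), MAF for alignments
(see :mod:`promvol.alignment`), GTF for gene models and TSV for tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

VCF_POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3- or 6-column BED file into a DataFrame."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED6_COLS[:3])
    df.columns = BED6_COLS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency, combined panel">
{pop_lines}
##INFO=<ID=ANC_TRUE,Number=1,Type=String,Description="True ancestral allele (simulation ground truth)">
##contig=<ID={contig},length={contig_len}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: pd.DataFrame, path: str | Path, contig: str = "chr1",
              contig_length: int = 0) -> None:
    """Write a minimal VCF v4.2 with combined and per-population AF INFO keys.

    Expects columns: chrom, pos (1-based), id, ref, alt, af, af_<pop> (lower
    case pop codes), anc_true (may be missing/NaN).
    """
    pop_lines = "\n".join(
        f'##INFO=<ID=AF_{p},Number=A,Type=Float,Description="Alternate allele frequency, {p}">'
        for p in VCF_POPULATIONS
    )
    if contig_length <= 0 and len(variants):
        contig_length = int(variants["pos"].max()) + 1000
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(pop_lines=pop_lines, contig=contig,
                                    contig_len=max(contig_length, 1)))
        for rec in variants.itertuples(index=False):
            info = [f"AF={rec.af:.6g}"]
            for p in VCF_POPULATIONS:
                v = getattr(rec, f"af_{p.lower()}", None)
                if v is not None and np.isfinite(v):
                    info.append(f"AF_{p}={v:.6g}")
            anc = getattr(rec, "anc_true", None)
            if isinstance(anc, str) and anc:
                info.append(f"ANC_TRUE={anc}")
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                     f"\t.\tPASS\t{';'.join(info)}\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF into a variant table (one row per record).

    Returns columns chrom, pos (1-based), id, ref, alt, af, af_<pop>,
    anc_true. Multi-ALT records are kept as single rows with comma-joined
    ALT; downstream filtering removes them as multi-allelic.
    """
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        alt = ",".join(v.ALT)
        row = {
            "chrom": v.CHROM,
            "pos": v.POS,
            "id": v.ID or ".",
            "ref": v.REF,
            "alt": alt,
            "af": _scalar(v.INFO.get("AF")),
            "anc_true": v.INFO.get("ANC_TRUE"),
        }
        for p in VCF_POPULATIONS:
            row[f"af_{p.lower()}"] = _scalar(v.INFO.get(f"AF_{p}"))
        rows.append(row)
    cols = ["chrom", "pos", "id", "ref", "alt", "af", "anc_true"] + [
        f"af_{p.lower()}" for p in VCF_POPULATIONS
    ]
    return pd.DataFrame(rows, columns=cols)


def _scalar(x):
    if x is None:
        return np.nan
    if isinstance(x, (tuple, list, np.ndarray)):
        return float(x[0])
    return float(x)


# ---------------------------------------------------------------------------
# GTF gene models

def write_gtf(gene_models: pd.DataFrame, path: str | Path) -> None:
    """Write transcript records (columns gene_id, transcript_id, chrom, start,
    end, strand) as a minimal GTF."""
    with open(path, "w") as fh:
        for rec in gene_models.itertuples(index=False):
            attrs = f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}";'
            fh.write(f"{rec.chrom}\tpromvol\ttranscript\t{rec.start + 1}\t{rec.end}"
                     f"\t.\t{rec.strand}\t.\t{attrs}\n")


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read transcript->gene links from a GTF (via gffutils)."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)
    rows = []
    for t in db.features_of_type("transcript"):
        rows.append({
            "gene_id": t.attributes["gene_id"][0],
            "transcript_id": t.attributes["transcript_id"][0],
            "chrom": t.seqid,
            "start": t.start - 1,
            "end": t.end,
            "strand": t.strand,
        })
    return pd.DataFrame(rows, columns=["gene_id", "transcript_id", "chrom",
                                       "start", "end", "strand"])
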