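"""End-to-end orchestration: simulate -> classify -> polarize -> selection ->
QTL -> expression CV -> traits, with one master seed fanned out per stage.

Every stage reads its inputs from, and writes its outputs to, the documented
interchange formats under the run directory, so stages can also be run (and
re-run) individually from the CLI. A run manifest records the config, seed
and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import __version__
from .alignment import AlignmentIndex, read_maf
from .classify import MousePromoterSet, annotate_promoters, classify_promoters
from .expression import compare_cv, cv_by_architecture, cv_table
from .polarize import exclusion_tally, polarize_variants, polarized_to_frame
from .qtl import (associate_qtl, attach_derived_beta, overlap_odds,
                  significant_molecular_qtl, tissue_consensus)
from .selection import (daf_results_to_frame, daf_test, per_population_daf,
                        collect_region_counts, spatial_enrichment)
from .synthetic import SimulationConfig, simulate_dataset, substream, write_fixtures
from .traits import (classify_variant_tracks, fit_covariate_model,
                     overlap_phenotype_variants)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "polarize", "selection", "qtl", "cv", "traits")

_PARAM_DEFAULTS = {
    "rare_max_daf": 0.015,
    "common_min_daf": 0.05,
    "promoter_halo": 50,
    "qtl_max_dist": 50,
    "rolling_window": 250,
    "neutral_flank": [2000, 4000],
    "flank_side_profile": "both",
    "flank_side_daf": "upstream",
    "profile_anchor": "tss",
    "n_boot_profile": 100,
    "n_boot_overlap": 1000,
    "n_perm": 1000,
    "alpha": 0.05,
}


@dataclass
class PipelineConfig:
    """Validated run configuration with the study's default parameters."""

    outdir: str = "promvol_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    simulation: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.params) - set(_PARAM_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        sim_fields = set(SimulationConfig.__dataclass_fields__)
        unknown = set(self.simulation) - sim_fields
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        self.params = {**_PARAM_DEFAULTS, **self.params}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # where results land does not change what they are
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run(config: PipelineConfig) -> dict:
    """Execute the requested stages; returns the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures = out / "fixtures"
    results = out / "results"
    results.mkdir(exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.hash(), "stages": {}}
    p = config.params

    current_stage = "setup"

    def stage_on(name):
        nonlocal current_stage
        if name in config.stages:
            current_stage = name
            logger.info("stage %s starting", name)
            return True
        return False

    try:
        if stage_on("simulate"):
            sim = SimulationConfig(**{**config.simulation,
                                      "seed": int(substream(config.seed, "simulate")
                                                  .integers(0, 2**31 - 1))})
            dataset = simulate_dataset(sim)
            write_fixtures(dataset, fixtures)
            manifest["stages"]["simulate"] = {
                "promoters": len(dataset.promoters),
                "variants": len(dataset.variants),
                "qtls": len(dataset.qtls),
                "genes": int(dataset.expression.shape[0]),
            }

        if stage_on("classify"):
            promoters = _read_promoter_bed(fixtures / "promoters.bed")
            index = AlignmentIndex(read_maf(fixtures / "alignments.maf"))
            mouse = MousePromoterSet(pio.read_bed(fixtures / "mouse_robust.bed"),
                                     pio.read_bed(fixtures / "mouse_permissive.bed"))
            classified = classify_promoters(promoters, index, mouse,
                                            max_dist=p["promoter_halo"])
            gene_links = pio.read_tsv(fixtures / "promoter_genes.tsv")
            classified = classified.merge(gene_links, on="id", how="left")
            gene_models = pio.read_gene_models(fixtures / "gene_models.gtf")
            classified = annotate_promoters(classified, index,
                                            gene_models=gene_models)
            pio.write_tsv(classified, results / "classified_promoters.tsv")
            manifest["stages"]["classify"] = dict(
                classified["history"].value_counts())

        if stage_on("polarize"):
            variants = pio.read_vcf(fixtures / "variants.vcf")
            index = AlignmentIndex(read_maf(fixtures / "alignments.maf"))
            polarized, log = polarize_variants(variants, index)
            frame = polarized_to_frame(polarized)
            pio.write_tsv(frame, results / "polarized_variants.tsv")
            pio.write_tsv(log, results / "polarize_exclusions.tsv")
            tally = exclusion_tally(polarized, log)
            n_in = len(variants)
            n_resolved = int(frame["resolution"].isin(["retained", "reversed"]).sum())
            manifest["stages"]["polarize"] = {
                "input": n_in, "resolved": n_resolved,
                "exclusions": dict(tally),
            }
            assert n_resolved + sum(tally.values()) == n_in

        if stage_on("selection"):
            classified = pio.read_tsv(results / "classified_promoters.tsv")
            frame = pio.read_tsv(results / "polarized_variants.tsv")
            usable = classified[classified["history"] != "unclassified"]
            profiles = {}
            for vc in ("SNP", "insertion", "deletion"):
                sub = frame[(frame["vclass"] == vc)
                            & frame["resolution"].isin(["retained", "reversed"])]
                if len(sub) == 0:
                    continue
                prof = spatial_enrichment(
                    sub["pos"].to_numpy() - 1, usable,
                    window=p["rolling_window"],
                    flank=tuple(p["neutral_flank"]),
                    n_boot=p["n_boot_profile"],
                    seed=int(substream(config.seed, "selection").integers(0, 2**31 - 1)),
                    anchor=p["profile_anchor"],
                    flank_side=p["flank_side_profile"])
                profiles[vc] = prof
                pio.write_tsv(prof.to_frame(), results / f"profile_{vc.lower()}.tsv")
            results_daf = per_population_daf(
                frame, usable, populations=("ALL",),
                alpha=p["alpha"], promoter_halo=p["promoter_halo"],
                neutral_flank=tuple(p["neutral_flank"]),
                flank_side=p["flank_side_daf"])
            results_daf += per_population_daf(
                frame, usable, alpha=p["alpha"],
                promoter_halo=p["promoter_halo"],
                neutral_flank=tuple(p["neutral_flank"]),
                flank_side=p["flank_side_daf"])
            daf_frame = daf_results_to_frame(results_daf)
            pio.write_tsv(daf_frame, results / "daf_tests.tsv")
            manifest["stages"]["selection"] = {
                "profiles": list(profiles), "daf_tests": len(daf_frame)}

        if stage_on("qtl"):
            classified = pio.read_tsv(results / "classified_promoters.tsv")
            frame = pio.read_tsv(results / "polarized_variants.tsv")
            qtls = pio.read_tsv(fixtures / "qtls.tsv")
            qtls["significant"] = [significant_molecular_qtl(b, s)
                                   for b, s in zip(qtls["beta"], qtls["se"])]
            sig = qtls[qtls["significant"]]
            usable = classified[classified["history"] != "unclassified"]
            assoc = associate_qtl(sig, usable, max_dist=p["qtl_max_dist"])
            flags = usable["id"].isin(assoc["promoter_id"]).to_numpy()
            odds = overlap_odds(usable, flags, alpha=p["alpha"])
            pio.write_tsv(pd.DataFrame([vars(o) for o in odds]),
                          results / "qtl_overlap_odds.tsv")
            withbeta = attach_derived_beta(assoc, frame)
            pio.write_tsv(withbeta, results / "qtl_derived_beta.tsv")
            consensus = {}
            hi = withbeta[(withbeta["history"] == "human_inserted")
                          & withbeta["derived_beta"].notna()]
            if len(hi):
                med = hi.groupby("tissue")["derived_beta"].median()
                if (med != 0).any():
                    n_red, n_tot, cp = tissue_consensus(med)
                    consensus = {"n_reduced": n_red, "n_total": n_tot, "p": cp}
            (results / "qtl_consensus.json").write_text(json.dumps(consensus))
            manifest["stages"]["qtl"] = {
                "qtls": len(qtls), "significant": int(qtls["significant"].sum()),
                "associated": len(assoc)}

        if stage_on("cv"):
            classified = pio.read_tsv(results / "classified_promoters.tsv")
            expression = pio.read_tsv(fixtures / "expression.tsv")
            cvs = cv_table(expression)
            pio.write_tsv(cvs, results / "cv.tsv")
            groups = cv_by_architecture(expression, classified)
            comp = compare_cv(groups)
            pio.write_tsv(comp, results / "cv_comparisons.tsv")
            manifest["stages"]["cv"] = {"genes": len(cvs), "comparisons": len(comp)}

        if stage_on("traits"):
            classified = pio.read_tsv(results / "classified_promoters.tsv")
            usable = classified[classified["history"] != "unclassified"].reset_index(drop=True)
            manifest_df = classify_variant_tracks(
                pio.read_tsv(fixtures / "track_manifest.tsv"))
            pio.write_tsv(manifest_df, results / "track_classes.tsv")
            genome_length = int(usable["end"].max() + 5_000)
            rows = []
            reg_results = {}
            for rec in manifest_df.itertuples(index=False):
                track = pio.read_bed(fixtures / rec.path)
                summaries = overlap_phenotype_variants(
                    usable, track, n_boot=p["n_boot_overlap"],
                    seed=int(substream(config.seed, "traits").integers(0, 2**31 - 1)),
                    genome_length=genome_length, n_perm=min(p["n_perm"], 200))
                for s in summaries:
                    rows.append({"track": rec.track,
                                 "variant_class": rec.variant_class, **vars(s)})
                from .traits import _overlap_flags
                response = _overlap_flags(usable, track).astype(int)
                if response.sum() and response.sum() < len(response):
                    fitres = fit_covariate_model(usable, response,
                                                 response_label=rec.track)
                    reg_results[rec.track] = {
                        t: {"beta": b, "p": pv, "zeroed": fitres.zeroed[t]}
                        for t, (b, pv) in fitres.coefficients.items()}
            pio.write_tsv(pd.DataFrame(rows), results / "trait_overlap.tsv")
            (results / "trait_regression.json").write_text(
                json.dumps(reg_results, indent=1, default=float))
            manifest["stages"]["traits"] = {"tracks": len(manifest_df)}
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{current_stage}' failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _read_promoter_bed(path: Path) -> pd.DataFrame:
    bed = pio.read_bed(path)
    bed = bed.rename(columns={"name": "id"})
    bed["tss"] = (bed["start"] + bed["end"]) // 2
    return bed[["id", "chrom", "start", "end", "strand", "tss"]]
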