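"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the statistical structure the downstream stages
assume, with every latent quantity recorded as truth:

* promoters on a single linear chromosome, each with a planted evolutionary
  history (conserved / functional_turnover / human_inserted / mouse_deleted);
* multi-species alignment blocks whose gap patterns encode those histories,
  plus per-variant mini-blocks carrying an explicit ancestral row;
* variants whose derived-allele counts are drawn from the Poisson-Random-
  Field (Sawyer-Hartl) site-frequency spectrum at a region-specific scaled
  selection coefficient gamma = 2Ns, and whose placement density follows a
  configurable mutation-rate profile around the TSS;
* QTL records with normal effect sizes and standard errors calibrated so a
  configurable fraction pass the |beta| > SE significance rule;
* an expression matrix with gene-architecture-conditional coefficients of
  variation; and phenotype-variant interval tracks with per-class overlap
  rates.

Each output table draws from its own named RNG substream of the master
seed, so adding one table never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .alignment import AlignmentBlock, SpeciesRow, write_maf

HISTORY_CLASSES = ("conserved", "functional_turnover", "human_inserted", "mouse_deleted")
OUTGROUP_SPECIES = ("dog", "horse", "cow", "pig")
BASES = np.frombuffer(b"ACGT", dtype="S1")
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: span of the variant field simulated around each TSS (bp each side); must
#: cover the 2-4 kb neutral-proxy flank
FIELD_HALF_SPAN = 4500
#: distance between consecutive promoter TSSs on the synthetic chromosome
PROMOTER_SPACING = 10_000
_MARGIN = 5_000


def substream(seed: int, name: str) -> np.random.Generator:
    """Named RNG substream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Site frequency spectrum under directional selection

def expected_sfs(gamma: float, sample_haplotypes: int) -> np.ndarray:
    """Probability of derived-allele count i in 1..n-1 under the
    Poisson-Random-Field stationary spectrum.

    f(q) is proportional to (1 - exp(-gamma (1-q))) / ((1 - exp(-gamma)) q (1-q))
    with the neutral gamma -> 0 limit f(q) proportional to 1/q. gamma = 2Ns.
    """
    if not np.isfinite(gamma):
        raise ValueError(f"selection coefficient gamma must be finite, got {gamma}")
    n = int(sample_haplotypes)
    if n < 4:
        raise ValueError("sample_haplotypes must be >= 4")
    q = np.arange(1, n) / n
    if abs(gamma) < 1e-9:
        w = 1.0 / q
    else:
        w = -np.expm1(-gamma * (1.0 - q)) / (-np.expm1(-gamma) * q * (1.0 - q))
    return w / w.sum()


def simulate_sfs_frequencies(n_sites: int, gamma: float, sample_haplotypes: int,
                             seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw derived-allele counts (in 1..n-1) iid from the discretized SFS."""
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    pmf = expected_sfs(gamma, sample_haplotypes)
    if n_sites == 0:
        return np.array([], dtype=np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(np.arange(1, int(sample_haplotypes)), size=n_sites, p=pmf)


# ---------------------------------------------------------------------------
# Alignment-block simulation

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def simulate_alignment_block(true_history: str, human_span: tuple[str, int, int],
                             block_length: int, seed: int | np.random.Generator = 0,
                             *, human_seq: str | None = None,
                             mouse_start: int = 0) -> AlignmentBlock:
    """Build a six-species block whose gap structure encodes a planted history.

    conserved / functional_turnover: every species aligns over the promoter
    span (the two differ only by mouse promoter activity, which lives in the
    mouse promoter BED, not the alignment). human_inserted: mouse and all
    four outgroups are gapped over the span. mouse_deleted: mouse is gapped,
    dog aligns (other outgroups at random). Flanks align in all species.
    """
    if true_history not in HISTORY_CLASSES:
        raise ValueError(f"unknown evolutionary history label: {true_history!r}")
    chrom, start, end = human_span
    span_len = end - start
    if block_length < span_len:
        raise ValueError("block_length must cover the human span")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pad_left = (block_length - span_len) // 2
    ref_start = start - pad_left
    if human_seq is None:
        human_seq = _random_seq(rng, block_length)
    elif len(human_seq) != block_length:
        raise ValueError("human_seq length must equal block_length")

    span_cols = (pad_left, pad_left + span_len)
    if true_history == "human_inserted":
        gapped = {"mouse", *OUTGROUP_SPECIES}
    elif true_history == "mouse_deleted":
        gapped = {"mouse"}
        for sp in ("horse", "cow", "pig"):  # dog always aligns: >=1 outgroup
            if rng.random() < 0.5:
                gapped.add(sp)
    else:
        gapped = set()

    rows = {"human": SpeciesRow(src=f"human.{chrom}", start=ref_start, text=human_seq)}
    cursor = mouse_start
    for sp in ("mouse",) + OUTGROUP_SPECIES:
        if sp in gapped:
            text = human_seq[: span_cols[0]] + "-" * span_len + human_seq[span_cols[1]:]
        else:
            text = human_seq
        rows[sp] = SpeciesRow(src=f"{sp}.chr1", start=cursor, text=text)
    return AlignmentBlock(rows=rows)


def simulate_classification_case(true_history: str, seed: int = 0):
    """One promoter + alignment block + mouse promoter set realizing a label.

    Convenience for round-trip checks: the mouse promoter set is built so
    that the classifier's robust/permissive distance rules resolve the
    aligned labels correctly.
    """
    from .classify import MousePromoterSet, Promoter

    rng = np.random.default_rng(seed)
    width = int(rng.integers(100, 301))
    start = 2_000
    end = start + width
    tss = (start + end) // 2
    mouse_start = 10_000
    block = simulate_alignment_block(true_history, ("chr1", start, end),
                                     width + 300, rng, mouse_start=mouse_start)
    prom = Promoter(id="P0", chrom="chr1", start=start, end=end,
                    strand="+" if rng.random() < 0.5 else "-", tss=tss)
    mouse_tss = mouse_start + (tss - block.ref_start)
    robust = permissive = pd.DataFrame(columns=["chrom", "start", "end"])
    if true_history == "conserved":
        d = int(rng.integers(0, 50))
        robust = pd.DataFrame([{"chrom": "chr1", "start": mouse_tss + d,
                                "end": mouse_tss + d + 100}])
        permissive = robust
    elif true_history == "functional_turnover":
        # decoy promoters well beyond the 50 bp rule
        robust = pd.DataFrame([{"chrom": "chr1", "start": mouse_tss + 500,
                                "end": mouse_tss + 600}])
        permissive = robust
    return prom, block, MousePromoterSet(robust=robust, permissive=permissive)


# ---------------------------------------------------------------------------
# Full dataset

def _default_gamma():
    return {"promoter": -5.0, "flank": 0.0, "background": 0.0}


def _default_qtl_rates():
    # sequence-turnover classes carry the planted molecular-QTL enrichment
    return {"conserved": 0.15, "functional_turnover": 0.08,
            "human_inserted": 0.30, "mouse_deleted": 0.30}


def _default_cv():
    # volatile-promoter genes get higher between-individual expression CV
    return {"conserved_only": 0.30, "functional_turnover": 0.45,
            "human_inserted": 0.45, "mouse_deleted": 0.45}


def _default_derived_beta_mean():
    # human-inserted promoters: derived alleles biased to reduced expression
    return {"conserved": 0.0, "functional_turnover": 0.0,
            "human_inserted": -0.1, "mouse_deleted": 0.0}


def _default_trait_rates():
    return {
        "gwas_catalog": {c: 0.15 for c in HISTORY_CLASSES},
        "clingen_cnv": {"conserved": 0.04, "functional_turnover": 0.04,
                        "human_inserted": 0.12, "mouse_deleted": 0.12},
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults state the simulated conditions."""

    n_promoters_per_class: int = 150
    genome_length: int | None = None          # bp; computed from layout if None
    sample_haplotypes: int = 5008             # 1000 Genomes phase-3 scale
    gamma_by_region: dict = field(default_factory=_default_gamma)
    mutation_rate_profile: list[tuple[int, int, float]] | None = None
    variant_rate: float = 0.02                # variants per bp around promoters
    indel_fraction: float = 0.15
    reversed_fraction: float = 0.20           # P(true ancestral allele = ALT)
    unresolved_fraction: float = 0.05         # P(window cannot resolve ancestry)
    qtl_rate_by_class: dict = field(default_factory=_default_qtl_rates)
    qtl_effect_sd: float = 0.5
    qtl_significant_fraction: float = 0.8
    qtl_derived_beta_mean_by_class: dict = field(default_factory=_default_derived_beta_mean)
    n_tissues: int = 5
    n_expression_samples: int = 100
    expression_cv_by_class: dict = field(default_factory=_default_cv)
    trait_rate_by_class: dict = field(default_factory=_default_trait_rates)
    seed: int = 0

    def validate(self) -> None:
        if self.n_promoters_per_class < 0:
            raise ValueError("n_promoters_per_class must be >= 0")
        if self.sample_haplotypes < 2:
            raise ValueError("sample_haplotypes must be >= 2")
        if self.mutation_rate_profile:
            for lo, hi, mult in self.mutation_rate_profile:
                if mult <= 0:
                    raise ValueError("rate multipliers must be > 0")
        for g in self.gamma_by_region.values():
            if not np.isfinite(g):
                raise ValueError("gamma values must be finite")
        n_total = self.n_promoters_per_class * len(HISTORY_CLASSES)
        if self.genome_length is not None:
            need = 2 * _MARGIN + n_total * PROMOTER_SPACING
            if self.genome_length < need:
                raise ValueError(
                    f"genome_length {self.genome_length} cannot host {n_total} "
                    f"promoters at {PROMOTER_SPACING} bp spacing (need >= {need})")

    @property
    def effective_genome_length(self) -> int:
        n_total = self.n_promoters_per_class * len(HISTORY_CLASSES)
        computed = 2 * _MARGIN + n_total * PROMOTER_SPACING
        return self.genome_length if self.genome_length is not None else computed


@dataclass
class SyntheticDataset:
    """In-memory bundle of all generated tables plus ground truth."""

    config: SimulationConfig
    promoters: pd.DataFrame
    mouse_robust: pd.DataFrame
    mouse_permissive: pd.DataFrame
    blocks: list
    variants: pd.DataFrame
    qtls: pd.DataFrame
    expression: pd.DataFrame
    gene_models: pd.DataFrame
    tracks: dict[str, pd.DataFrame]
    track_manifest: pd.DataFrame


def _profile_weights(profile, offsets: np.ndarray) -> np.ndarray:
    w = np.ones(offsets.shape)
    if profile:
        for lo, hi, mult in profile:
            w[(offsets >= lo) & (offsets < hi)] = mult
    return w


def _choose_alt(ref: str, rng: np.random.Generator) -> str:
    """SNP alternate allele with a 2:1 transition:transversion ratio."""
    if rng.random() < 2.0 / 3.0:
        return TRANSITION[ref]
    others = [b for b in "ACGT" if b != ref and b != TRANSITION[ref]]
    return others[int(rng.integers(0, 2))]


def _variant_block(chrom: str, pos0: int, ref: str, alt: str, vclass: str,
                   resolution: str, genome: np.ndarray,
                   rng: np.random.Generator) -> AlignmentBlock:
    """Human + ancestral mini-block (variant span +/- 2 bp) encoding truth."""
    lo = pos0 - 2
    hi = pos0 + len(ref) + 2
    human = genome[lo:hi].tobytes().decode()
    anc = list(human)
    center = 2
    if vclass == "SNP":
        if resolution == "reversed":
            anc[center] = alt
        elif resolution == "excluded":
            if rng.random() < 0.5:
                anc[center] = [b for b in "ACGT" if b not in (ref, alt)][0]
            else:
                anc[center] = "-"  # gapped window -> removed
        anc_text, human_text = "".join(anc), human
    elif vclass == "insertion":
        k = len(alt) - len(ref)
        if resolution == "reversed":
            # ancestral carries the inserted bases: human row gets gap columns
            human_text = human[: center + 1] + "-" * k + human[center + 1:]
            anc_text = human[: center + 1] + alt[len(ref):] + human[center + 1:]
        elif resolution == "excluded":
            j = k + 1
            human_text = human[: center + 1] + "-" * j + human[center + 1:]
            anc_text = human[: center + 1] + _random_seq(rng, j) + human[center + 1:]
        else:
            anc_text, human_text = human, human
    else:  # deletion
        k = len(ref) - len(alt)
        if resolution == "reversed":
            anc = anc[: center + 1] + ["-"] * k + anc[center + 1 + k:]
            anc_text, human_text = "".join(anc), human
        elif resolution == "excluded":
            j = k + 1
            human_text = human[: center + 1] + "-" * j + human[center + 1:]
            anc_text = human[: center + 1] + _random_seq(rng, j) + human[center + 1:]
        else:
            anc_text, human_text = human, human
    rows = {
        "human": SpeciesRow(src=f"human.{chrom}", start=lo, text=human_text),
        "ancestral": SpeciesRow(src="ancestral.chr1", start=0, text=anc_text),
    }
    return AlignmentBlock(rows=rows)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full ground-truthed dataset described by `config`."""
    config.validate()
    seed = config.seed
    chrom = "chr1"
    n_total = config.n_promoters_per_class * len(HISTORY_CLASSES)
    genome_length = config.effective_genome_length

    rng_layout = substream(seed, "layout")
    rng_seq = substream(seed, "sequence")
    rng_var = substream(seed, "variants")
    rng_qtl = substream(seed, "qtls")
    rng_expr = substream(seed, "expression")
    rng_trait = substream(seed, "traits")
    rng_genes = substream(seed, "genes")

    genome = rng_seq.choice(BASES, size=genome_length)

    # --- promoters -----------------------------------------------------
    labels = np.repeat(HISTORY_CLASSES, config.n_promoters_per_class)
    labels = labels[rng_layout.permutation(n_total)]
    prom_rows, blocks = [], []
    mouse_robust_rows, mouse_permissive_rows = [], []
    mouse_cursor = 1_000
    for i in range(n_total):
        center = _MARGIN + i * PROMOTER_SPACING + PROMOTER_SPACING // 2
        width = int(rng_layout.integers(100, 301))
        start = center - width // 2
        end = start + width
        tss = (start + end) // 2
        strand = "+" if rng_layout.random() < 0.5 else "-"
        history = str(labels[i])
        block_length = width + 300
        ref_start = start - (block_length - width) // 2
        human_seq = genome[ref_start: ref_start + block_length].tobytes().decode()
        block = simulate_alignment_block(history, (chrom, start, end), block_length,
                                         rng_layout, human_seq=human_seq,
                                         mouse_start=mouse_cursor)
        blocks.append(block)
        mouse_tss = mouse_cursor + (tss - ref_start)
        if history == "conserved":
            d = int(rng_layout.integers(0, 50))
            mouse_robust_rows.append((chrom, mouse_tss + d, mouse_tss + d + 100))
            mouse_permissive_rows.append((chrom, mouse_tss + d, mouse_tss + d + 100))
        elif history == "functional_turnover":
            # decoys far beyond the 50 bp neighbourhood
            mouse_robust_rows.append((chrom, mouse_tss + 500, mouse_tss + 600))
            mouse_permissive_rows.append((chrom, mouse_tss + 700, mouse_tss + 800))
        mouse_cursor += block_length + 1_000
        prom_rows.append({"id": f"P{i:05d}", "chrom": chrom, "start": start,
                          "end": end, "strand": strand, "tss": tss,
                          "history": history})
    promoters = pd.DataFrame(prom_rows, columns=["id", "chrom", "start", "end",
                                                 "strand", "tss", "history"])

    # --- gene links (some genes host two promoters) ---------------------
    gene_ids = []
    g = 0
    i = 0
    while i < n_total:
        gid = f"G{g:05d}"
        gene_ids.append(gid)
        if i + 1 < n_total and rng_genes.random() < 0.3:
            gene_ids.append(gid)
            i += 2
        else:
            i += 1
        g += 1
    promoters["gene_id"] = gene_ids[:n_total]

    gene_model_rows = []
    for gid, sub in promoters.groupby("gene_id", sort=True):
        n_tx = int(rng_genes.integers(1, 9))
        gstart = int(sub["start"].min())
        gend = int(sub["end"].max()) + 2_000
        for t in range(n_tx):
            gene_model_rows.append({"gene_id": gid, "transcript_id": f"{gid}.T{t}",
                                    "chrom": chrom, "start": gstart, "end": gend,
                                    "strand": str(sub["strand"].iloc[0])})
    gene_models = pd.DataFrame(gene_model_rows,
                               columns=["gene_id", "transcript_id", "chrom",
                                        "start", "end", "strand"])

    # --- variants --------------------------------------------------------
    offsets = np.arange(-FIELD_HALF_SPAN, FIELD_HALF_SPAN + 1)
    weights = _profile_weights(config.mutation_rate_profile, offsets)
    pmf_cache = {lab: expected_sfs(gam, config.sample_haplotypes)
                 for lab, gam in config.gamma_by_region.items()}
    count_support = np.arange(1, config.sample_haplotypes)
    var_rows = []
    vid = 0
    for p in promoters.itertuples(index=False):
        n_exp = config.variant_rate * weights.sum()
        n_here = int(rng_var.poisson(n_exp))
        n_here = min(n_here, offsets.size)
        offs = rng_var.choice(offsets, size=n_here, replace=False,
                              p=weights / weights.sum())
        offs.sort()
        for off in offs:
            pos0 = int(p.tss + off)
            if pos0 < 12 or pos0 > genome_length - 16:
                continue
            if p.start - 50 <= pos0 < p.end + 50:
                region = "promoter"
            elif 2_000 <= abs(off) <= 4_000:
                region = "flank"
            else:
                region = "background"
            u = rng_var.random()
            if u < config.indel_fraction / 2:
                vclass = "insertion"
            elif u < config.indel_fraction:
                vclass = "deletion"
            else:
                vclass = "SNP"
            ref_base = genome[pos0].decode()
            if vclass == "SNP":
                ref, alt = ref_base, _choose_alt(ref_base, rng_var)
            elif vclass == "insertion":
                k = int(rng_var.integers(1, 11))
                ref, alt = ref_base, ref_base + _random_seq(rng_var, k)
            else:
                k = int(rng_var.integers(1, 11))
                ref = genome[pos0: pos0 + k + 1].tobytes().decode()
                alt = ref_base
            count = int(rng_var.choice(count_support, p=pmf_cache[region]))
            daf = count / config.sample_haplotypes
            if rng_var.random() < config.unresolved_fraction:
                resolution = "excluded"
                anc_true = ""
            elif rng_var.random() < config.reversed_fraction:
                resolution, anc_true = "reversed", alt
            else:
                resolution, anc_true = "retained", ref
            af_alt = 1.0 - daf if resolution == "reversed" else daf
            row = {"chrom": chrom, "pos": pos0 + 1, "id": f"rs{vid:07d}",
                   "ref": ref, "alt": alt, "vclass": vclass, "af": af_alt,
                   "anc_true": anc_true, "true_daf": daf, "region": region,
                   "true_resolution": resolution, "promoter_id": p.id}
            for pop in pio.VCF_POPULATIONS:
                row[f"af_{pop.lower()}"] = float(
                    np.clip(af_alt + rng_var.normal(0.0, 0.01), 0.0, 1.0))
            var_rows.append(row)
            vid += 1
    variant_cols = ["chrom", "pos", "id", "ref", "alt", "vclass", "af",
                    "anc_true", "true_daf", "region", "true_resolution",
                    "promoter_id"] + [f"af_{p.lower()}" for p in pio.VCF_POPULATIONS]
    variants = pd.DataFrame(var_rows, columns=variant_cols)
    # one variant record per position (the pipeline drops multi-variant sites)
    variants = variants.drop_duplicates(subset=["chrom", "pos"], keep="first")
    variants = variants.reset_index(drop=True)
    for v in variants.itertuples(index=False):
        blocks.append(_variant_block(v.chrom, v.pos - 1, v.ref, v.alt, v.vclass,
                                     v.true_resolution, genome, rng_var))

    # --- QTLs ------------------------------------------------------------
    tissues = [f"tissue_{t:02d}" for t in range(config.n_tissues)]
    near_tss = {}
    if len(variants):
        for p in promoters.itertuples(index=False):
            sub = variants[(variants["promoter_id"] == p.id)
                           & ((variants["pos"] - 1 - p.tss).abs() <= 50)]
            if len(sub):
                near_tss[p.id] = sub
    qtl_rows = []
    for p in promoters.itertuples(index=False):
        if p.id not in near_tss:
            continue
        cand = near_tss[p.id]
        rate = config.qtl_rate_by_class.get(p.history, 0.0)
        mu = config.qtl_derived_beta_mean_by_class.get(p.history, 0.0)
        for tissue in tissues:
            if rng_qtl.random() >= rate:
                continue
            v = cand.iloc[int(rng_qtl.integers(0, len(cand)))]
            derived_beta = float(rng_qtl.normal(mu, config.qtl_effect_sd))
            beta = derived_beta if v["true_resolution"] != "reversed" else -derived_beta
            if rng_qtl.random() < config.qtl_significant_fraction:
                se = abs(beta) * float(rng_qtl.uniform(0.2, 0.95))
            else:
                se = abs(beta) * float(rng_qtl.uniform(1.05, 2.0))
            qtl_rows.append({"variant_id": v["id"], "chrom": chrom,
                             "pos": int(v["pos"]), "ref": v["ref"], "alt": v["alt"],
                             "phenotype_id": p.gene_id, "tissue": tissue,
                             "beta": beta, "se": se})
    qtls = pd.DataFrame(qtl_rows, columns=["variant_id", "chrom", "pos", "ref",
                                           "alt", "phenotype_id", "tissue",
                                           "beta", "se"])

    # --- expression ------------------------------------------------------
    sample_ids = [f"S{j:04d}" for j in range(config.n_expression_samples)]
    expr_rows = []
    for gid, sub in promoters.groupby("gene_id", sort=True):
        volatile = [h for h in sub["history"].unique() if h != "conserved"]
        if volatile:
            cv = max(config.expression_cv_by_class.get(h, 0.45) for h in volatile)
        else:
            cv = config.expression_cv_by_class.get("conserved_only", 0.30)
        mean = float(rng_expr.lognormal(np.log(10.0), 1.0))
        shape = 1.0 / cv ** 2
        vals = rng_expr.gamma(shape, mean / shape, size=config.n_expression_samples)
        expr_rows.append([gid] + list(np.round(vals, 4)))
    expression = pd.DataFrame(expr_rows, columns=["gene_id"] + sample_ids)

    # --- phenotype-variant tracks ---------------------------------------
    tracks = {}
    manifest_rows = []
    descriptions = {"gwas_catalog": "GWAS Catalog trait-associated SNPs",
                    "clingen_cnv": "ClinGen likely pathogenic cnv DelDup calls"}
    for track, rates in config.trait_rate_by_class.items():
        rows = []
        for p in promoters.itertuples(index=False):
            if rng_trait.random() < rates.get(p.history, 0.0):
                s = int(rng_trait.integers(p.start - 200, p.end - 10))
                w = int(rng_trait.integers(20, 400))
                rows.append((chrom, max(s, 0), min(s + w, genome_length)))
            # background intervals keep permutation baselines honest
            if rng_trait.random() < 0.05:
                s = int(p.end + 4_600)
                rows.append((chrom, s, s + 100))
        tracks[track] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        manifest_rows.append({"track": track, "path": f"tracks/{track}.bed",
                              "description": descriptions.get(track, track)})
    track_manifest = pd.DataFrame(manifest_rows, columns=["track", "path",
                                                          "description"])

    return SyntheticDataset(
        config=config,
        promoters=promoters,
        mouse_robust=pd.DataFrame(mouse_robust_rows, columns=["chrom", "start", "end"]),
        mouse_permissive=pd.DataFrame(mouse_permissive_rows,
                                      columns=["chrom", "start", "end"]),
        blocks=blocks,
        variants=variants,
        qtls=qtls,
        expression=expression,
        gene_models=gene_models,
        tracks=tracks,
        track_manifest=track_manifest,
    )


def write_fixtures(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset to disk in the pipeline's interchange formats."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        (d / "tracks").mkdir(exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create fixture directory {d}: {e}") from e
    paths = {}

    prom_bed = dataset.promoters.assign(score=0)[
        ["chrom", "start", "end", "id", "score", "strand"]
    ].rename(columns={"id": "name"})
    paths["promoters"] = d / "promoters.bed"
    pio.write_bed(prom_bed, paths["promoters"])

    for name, df in (("mouse_robust", dataset.mouse_robust),
                     ("mouse_permissive", dataset.mouse_permissive)):
        paths[name] = d / f"{name}.bed"
        pio.write_bed(df, paths[name])

    paths["alignments"] = d / "alignments.maf"
    write_maf(dataset.blocks, paths["alignments"])

    paths["variants"] = d / "variants.vcf"
    pio.write_vcf(dataset.variants, paths["variants"],
                  contig_length=dataset.config.effective_genome_length)

    paths["qtls"] = d / "qtls.tsv"
    pio.write_tsv(dataset.qtls, paths["qtls"])

    paths["expression"] = d / "expression.tsv"
    pio.write_tsv(dataset.expression, paths["expression"])

    paths["gene_models"] = d / "gene_models.gtf"
    pio.write_gtf(dataset.gene_models, paths["gene_models"])

    for track, df in dataset.tracks.items():
        paths[track] = d / "tracks" / f"{track}.bed"
        pio.write_bed(df, paths[track])
    paths["track_manifest"] = d / "track_manifest.tsv"
    pio.write_tsv(dataset.track_manifest, paths["track_manifest"])

    # promoter -> gene association table (analysis input, not truth)
    paths["promoter_genes"] = d / "promoter_genes.tsv"
    pio.write_tsv(dataset.promoters[["id", "gene_id"]], paths["promoter_genes"])

    paths["truth_promoters"] = d / "truth_promoters.tsv"
    pio.write_tsv(dataset.promoters, paths["truth_promoters"])
    paths["truth_variants"] = d / "truth_variants.tsv"
    pio.write_tsv(dataset.variants, paths["truth_variants"])

    import yaml

    paths["config"] = d / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump({"simulation": asdict(dataset.config)}, fh)
    return paths
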