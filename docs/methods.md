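# Methods

## Overview

`promvol` implements a promoter-centric population-genetics pipeline in
seven stages: synthetic-data generation, evolutionary-history
classification, ancestral-state polarization, selection inference,
QTL enrichment, expression-variability comparison, and trait-variant
overlap/regression. This note records the models, the parameter defaults
(with the reasons for them), the numerical choices, and the limits of what
the synthetic data can demonstrate.

## Evolutionary-history classification

A promoter is a strand-aware CAGE tag-cluster interval `[start, end)` with a
representative TSS (the cluster midpoint unless a summit is supplied; the
midpoint is the only choice that is well defined for every cluster). The
TSS is projected through six-species whole-genome alignment blocks (human,
mouse, dog, horse, cow, pig):

* **conserved** — the TSS column is aligned (non-gap) in mouse and the
  projected mouse position is within 50 bp (inclusive) of a robust mouse
  promoter. Distance is measured to the nearest interval *edge*: edge
  distance is the only monotone choice when cluster widths vary.
* **functional_turnover** — aligned in mouse, but > 50 bp from both robust
  and permissive mouse promoters: the sequence survives, the activity does
  not.
* **mouse_deleted** — not aligned in mouse but aligned in ≥ 1 outgroup:
  ancestrally present, lost on the mouse lineage.
* **human_inserted** — aligned in no non-human species: the
  promoter-bearing sequence arose on the human lineage.
* **unclassified** — aligned in mouse within 50 bp of a permissive-only
  promoter (an ambiguous activity call: neither conserved activity nor
  clear absence), or a chromosome missing from the alignment index. These
  promoters are dropped from downstream contrasts and their counts logged.

Covariates for the regression stage: GC count (number of G/C bases in the
cluster), CpG-island and repeat overlap (≥ 1 bp, half-open arithmetic),
isoform count of the linked gene (number of annotated transcripts;
unlinked promoters get 0 and a flag), and a TATA-box call.

### TATA scan

The scanner slides an 8-column TATA-box (TATAWAWR) position-weight matrix —
a hand-curated, synthetic TBP-site-like count matrix packaged with the code
— over both strands of the −30..−20 region upstream of the TSS. A window is
a hit when the exact p-value of its log-odds score is below 10⁻³. The
p-value is exact by construction: the full score distribution over all 4⁸
k-mers is enumerated under a 0-order background estimated from the scanned
sequence (uniform fallback when a base is absent). No external motif
software or database matrix is used.

## Ancestral-state polarization

For each variant the span of the REF allele ± 2 bp is projected through the
alignment and the ancestral row recorded. When several blocks cover the
window, the one with the most closely related ancestral source wins (an
explicit ancestral-reconstruction row beats any outgroup, then mouse before
the more distant outgroups); ties are broken toward the narrowest block
centred on the variant — the most local ancestral context.

* SNPs: excluded if unaligned or any gap occurs in the 5 bp window;
  otherwise the ancestral base at the variant column decides — REF →
  *retained* (ALT is derived), ALT → *reversed* (REF is derived), any third
  base → excluded. Any other rule would invent an unobserved allele.
* Indels: gaps are stripped from the ancestral window and only its *length*
  is compared (never sequence identity) with the window lengths implied by
  the REF and ALT alleles (allele length + 4). Matching REF retains the
  annotated insertion/deletion type; matching ALT reverses it; neither →
  excluded.

Pre-polarization filters remove multi-mapping records and positions with
more than one variant record. Exclusions carry one reason each, assigned in
the fixed order multi-mapping → multi-allelic → unaligned → gapped window →
unresolvable, and the stage asserts that retained + reversed + excluded
reconciles with the input count.

DAF = 1 − frequency(ancestral allele), computed for the combined panel and
the five super-populations (AFR, AMR, EAS, EUR, SAS) when present; a
missing population frequency silently omits that population rather than
erroring. Classes: rare (DAF < 1.5%), common (DAF > 5%), intermediate
otherwise — strict inequalities, so 1.5% and 5% are intermediate.

## Selection inference

**Enrichment metaprofiles.** Event rates (variants, QTLs) are averaged in a
centered 250 bp rolling window at every 1 bp offset from the anchor,
truncated at the span edges, pooled over promoters after orientation-
flipping minus-strand anchors, and divided by the mean rate over the 2–4 kb
flanks. The flank mean of the normalized profile is exactly 1 by
construction. Confidence bands are percentile intervals from resampling
*promoters* (not events) with replacement, 100 replicates by default. The
anchor is the TSS by default (midpoint optional), and the normalizer uses
both flanks for profiles but the upstream flank only for DAF tests — the
upstream flank is the cleaner neutral proxy as it avoids the transcribed
region; both are configurable.

**DAF test.** Counts of rare and common derived alleles in the merged union
of promoter ± 50 bp halos are compared with those in the merged
neutral-proxy flanks (a variant inside a halo is never double counted in
the flank) via a two-sided Fisher's exact test. The reported odds ratio is
the conditional maximum-likelihood estimate under Fisher's noncentral
hypergeometric distribution, with the exact (Cornfield) confidence
interval; the cross-product sample OR is reported alongside. The CI level
is Bonferroni-adjusted to 1 − α/m for a family of m tests — m defaults to
the number of tests emitted in one invocation (e.g. 15 for five category
sets × three mutation types at family-wise 95%, i.e. 99.7% per test). The
conditional inference is implemented in `promvol.exact` with a vectorized
log-pmf over the conditional support and Brent root-finding; it matches
`scipy.stats.contingency.odds_ratio(kind="conditional")` to ≤ 10⁻⁴
relative error (cross-checked in the test suite) and stays fast for cell
counts in the thousands. Degenerate tables (a zero margin) are flagged and
reported with p = 1 and no OR rather than raising.

## QTL enrichment

A molecular QTL is significant when |β| > SE. The absolute value matters: a
signed reading would discard all negative effects, which is inconsistent
with effect-size distributions being two-sided. QTLs associate with every
promoter whose TSS is within 50 bp (inclusive); equidistant QTLs map to all
such promoters. Per-class overlap enrichment is an exact conditional odds
ratio against the conserved class (or a shuffled-genome baseline built from
length-preserving uniform permutation).

Effect sizes are re-signed to the ancestral → derived direction:
`derived_beta = +β` for retained variants, `−β` for reversed, absent for
excluded. The tissue-consensus test counts tissues whose median derived β
is negative (medians of exactly 0 are dropped and logged) and compares the
observed (reduced, increased) split against an expected 50:50 split of the
same total with Fisher's exact test — the 2×2 construction that reproduces
the test's intended null. Group-level comparisons of derived-β
distributions use two-sided Mann–Whitney tests, with the exact null
distribution whenever both groups are small (≤ 25) and tie-free, and
Bonferroni correction capped at 1.

## Expression variability

Per gene, CV = sample standard deviation (n−1 denominator) / mean across
samples, computed for genes expressed (> 0) in at least 10 samples.
"Expressed" means strictly positive because RPKM 0 is the natural
lower bound and any positive threshold would be arbitrary. After the
≥ 10-expressed filter, mean and SD are taken over *all* samples — the
simplest reading of the definition; a variant restricted to expressed
samples is implemented and exposed side by side
(`use_expressed_only=True`).

Genes are grouped by promoter architecture: `conserved_only` as reference,
and per volatile class a `+conserved` / `−conserved` stratum; a gene with k
volatile classes contributes to k groups. Tissue-level CV tables aggregate
via the per-gene median CV across tissues.

## Trait overlap and regression

Per-category percent overlap with merged phenotype-variant tracks carries a
1000-resample promoter bootstrap CI, with baseline bands from genome-wide
permuted promoter positions (uniform, length-preserving, no exclusion
zones — the synthetic genome has no assembly gaps; real-genome runs accept
an exclusion set) and from the all-variant track. Tracks are labelled
structural when their name/description contains a CNV / DelDup / ClinVar /
indel marker (case-insensitive substring), sequence otherwise.

The enrichment model is a binomial-family GLM with logit link on a binary
overlap response with history (conserved as reference level), GC count,
CpG, TATA, repeat and isoform count as covariates. Coefficients with
p > 0.05 are *reported* as 0, but the raw fit is always retained — the
zeroing is a pure post-processing map. Complete separation is caught:
coefficients with |β| > 15 or undefined p are flagged unestimable and
zeroed rather than reported as huge numbers.

## Synthetic data: what it emulates, and what it does not

One linear chromosome. Promoters (width 100–300 bp, random strand) sit on a
10 kb grid so each carries a non-overlapping ± 4.5 kb variant field covering
the 2–4 kb flank. Alignment gap structure encodes the planted history;
per-variant mini-blocks carry an explicit ancestral row encoding the
recorded ancestral allele (including planted unresolvable and gapped-window
cases). Defaults state the simulated study conditions:

| parameter | default | rationale |
|---|---|---|
| `sample_haplotypes` | 5008 | 1000 Genomes phase-3 scale |
| `gamma_by_region` | promoter −5, flank 0, background 0 | purifying selection at promoters against a neutral flank, the regime the DAF test is designed to detect |
| `variant_rate` | 0.02 /bp | order of the human polymorphism density in large panels |
| `indel_fraction` | 0.15, lengths 1–10 bp uniform | indels are a minority of small variants |
| `reversed_fraction` | 0.20 | a minority of sites where the reference carries the derived allele |
| `unresolved_fraction` | 0.05 | windows planted unresolvable, to exercise exclusion paths |
| `qtl_rate_by_class` | conserved 0.15, functional-turnover 0.08, human-inserted/mouse-deleted 0.30 | molecular-QTL enrichment planted in the sequence-turnover classes |
| `qtl_significant_fraction` | 0.8 | fraction passing |β| > SE |
| `qtl_derived_beta_mean_by_class` | human-inserted −0.1, others 0 | derived-allele bias toward reduced expression at human-inserted promoters |
| `expression_cv_by_class` | conserved-only 0.30, volatile 0.45 | higher between-individual expression CV for volatile-promoter genes |
| transition:transversion | 2:1 | typical genome-wide ratio |

Each output table draws from a named RNG substream of the master seed
(`SeedSequence([seed, crc32(name)])`), so adding or resizing one table
never perturbs another, and identical configs produce byte-identical
fixture files.

Derived-allele counts are drawn i.i.d. from the discretized
Poisson-Random-Field stationary SFS; the γ → 0 limit is the 1/q neutral
spectrum (|γ| < 10⁻⁹ switches to the closed form; elsewhere `expm1` keeps
the ratio stable). The generator does **not** emulate linkage
disequilibrium, recombination, demography, coalescent genealogies, CpG
hypermutability, or sequence-level realism of repeats and CpG islands
(interval labels only). Passing tests therefore demonstrate correctness of
the *inference machinery* under the stated generative model — recovery of
planted selection coefficients, enrichment rates and class labels — not
robustness to the correlation structure of real population data.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately compact problem
sizes chosen as the smallest at which the checked effects are
deterministic or well-powered: 60-promoter datasets (~10⁴ variants) for
polarization and profile recovery, 1000 blocks per class for the
classification round-trip, 100/500 replicates for DAF-test power and null
CI calibration at 5000 variants per region, and 50 replicates of n = 10⁴
GLM fits. The rolling window (250 bp) is even, so the "centre" sits half a
base left of the window midpoint; profiles are reported on the 1 bp offset
grid and this half-base asymmetry is far below the window scale. Bootstrap
bands use percentile intervals; replicates whose resample empties the
flank normalizer are dropped as NaN. Exact-CI root-finding brackets
log ψ in ±80, well beyond any attainable conditional MLE.

## Known limitations

* Functional-turnover calls inherit the mouse promoter catalogue's
  completeness; the permissive-only "unclassified" bucket quantifies but
  does not resolve the ambiguity.
* The DAF test treats variants as independent; linkage disequilibrium makes
  its p-values anti-conservative on real population data. This is a
  property of the test itself, not of this implementation.
* The conditional-MLE odds ratio is undefined when any margin is zero;
  such tables are flagged rather than estimated.
* The synthetic QTL stage plants promoter-proximal effects only; trans- or
  distal-QTL architectures are out of scope.
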