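import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_overlap
from promvol import io as pio
from promvol.alignment import AlignmentBlock, AlignmentIndex, SpeciesRow
from promvol.classify import (MousePromoterSet, Promoter, annotate_overlaps,
                              assign_isoform_count, classify_promoter,
                              classify_promoters, compute_gc_count, scan_tata)
from promvol.synthetic import simulate_classification_case

EMPTY = pd.DataFrame(columns=["chrom", "start", "end"])


def _block(mouse_gap=False, outgroup_gaps=(), width=200, start=1000,
           mouse_start=500):
    seq = "ACGT" * (width // 4)
    rows = {"human": SpeciesRow(src="human.chr1", start=start, text=seq)}
    for sp in ("mouse", "dog", "horse", "cow", "pig"):
        gapped = (sp == "mouse" and mouse_gap) or sp in outgroup_gaps
        text = "-" * width if gapped else seq
        rows[sp] = SpeciesRow(src=f"{sp}.chr1",
                              start=mouse_start if sp == "mouse" else 0,
                              text=text)
    return AlignmentBlock(rows=rows)


def _promoter(tss=1100):
    return Promoter(id="P", chrom="chr1", start=tss - 50, end=tss + 50, tss=tss)


class TestClassifyBranches:
    def test_aligned_at_robust_promoter_is_conserved(self):
        # projected mouse position sits inside a robust promoter: distance 0
        idx = AlignmentIndex([_block()])
        mpos = 500 + 100  # ungapped block: offset preserved
        robust = pd.DataFrame([{"chrom": "chr1", "start": mpos - 10,
                                "end": mpos + 10}])
        mouse = MousePromoterSet(robust, robust)
        assert classify_promoter(_promoter(), idx, mouse) == "conserved"

    def test_aligned_far_from_any_promoter_is_functional_turnover(self):
        idx = AlignmentIndex([_block()])
        far = pd.DataFrame([{"chrom": "chr1", "start": 5000, "end": 5100}])
        mouse = MousePromoterSet(far, far)
        assert classify_promoter(_promoter(), idx, mouse) == "functional_turnover"

    def test_distance_rule_is_inclusive_at_50(self):
        idx = AlignmentIndex([_block()])
        mpos = 600
        at_50 = pd.DataFrame([{"chrom": "chr1", "start": mpos + 50,
                               "end": mpos + 150}])
        mouse = MousePromoterSet(at_50, at_50)
        assert classify_promoter(_promoter(), idx, mouse) == "conserved"
        at_51 = pd.DataFrame([{"chrom": "chr1", "start": mpos + 51,
                               "end": mpos + 151}])
        mouse = MousePromoterSet(at_51, at_51)
        assert classify_promoter(_promoter(), idx, mouse) == "functional_turnover"

    def test_projects_to_no_species_is_human_inserted(self):
        idx = AlignmentIndex([_block(mouse_gap=True,
                                     outgroup_gaps=("dog", "horse", "cow", "pig"))])
        mouse = MousePromoterSet(EMPTY, EMPTY)
        assert classify_promoter(_promoter(), idx, mouse) == "human_inserted"

    def test_projects_to_dog_only_is_mouse_deleted(self):
        idx = AlignmentIndex([_block(mouse_gap=True,
                                     outgroup_gaps=("horse", "cow", "pig"))])
        mouse = MousePromoterSet(EMPTY, EMPTY)
        assert classify_promoter(_promoter(), idx, mouse) == "mouse_deleted"

    def test_permissive_only_neighbourhood_is_unclassified(self):
        idx = AlignmentIndex([_block()])
        mpos = 600
        near = pd.DataFrame([{"chrom": "chr1", "start": mpos - 10, "end": mpos + 10}])
        far = pd.DataFrame([{"chrom": "chr1", "start": 5000, "end": 5100}])
        mouse = MousePromoterSet(robust=far, permissive=near)
        assert classify_promoter(_promoter(), idx, mouse) == "unclassified"

    def test_missing_chromosome_warns_not_raises(self, caplog):
        idx = AlignmentIndex([_block()])
        mouse = MousePromoterSet(EMPTY, EMPTY)
        p = Promoter(id="P", chrom="chrUn", start=0, end=100)
        assert classify_promoter(p, idx, mouse) == "unclassified"

    def test_round_trip_on_simulated_blocks(self):
        for label in ("conserved", "functional_turnover", "human_inserted",
                      "mouse_deleted"):
            for seed in range(25):
                prom, block, mouse = simulate_classification_case(label, seed)
                got = classify_promoter(prom, AlignmentIndex([block]), mouse)
                assert got == label, (label, seed)


class TestClassifyInvariants:
    def test_partition_and_order_invariance(self, small_dataset, alignment_index):
        mouse = MousePromoterSet(small_dataset.mouse_robust,
                                 small_dataset.mouse_permissive)
        prom = small_dataset.promoters
        got = classify_promoters(prom, alignment_index, mouse)
        assert (got["history"] == prom["history"]).all()  # diagonal confusion
        shuffled = prom.sample(frac=1, random_state=1)
        got2 = classify_promoters(shuffled, alignment_index, mouse)
        merged = got2.merge(got[["id", "history"]], on="id", suffixes=("_s", ""))
        assert (merged["history_s"] == merged["history"]).all()


class TestGCCount:
    @pytest.mark.parametrize("seq,expected", [
        ("GCGC", 4), ("ATAT", 0), ("", 0), ("gcAT", 2), ("ANNNC", 1),
    ])
    def test_counts(self, seq, expected):
        assert compute_gc_count(seq) == expected

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            compute_gc_count("ACGU")


class TestTataScan:
    def test_canonical_tata_found(self):
        # TATAAAAG is the PWM consensus; embed at the scan window
        assert scan_tata("GGG" + "TATAAAAG" + "GGG")

    def test_all_g_not_found(self):
        assert not scan_tata("G" * 20)

    def test_reverse_strand_found(self):
        import promvol.classify as c
        rc = "TATAAAAG".translate(c._COMPLEMENT)[::-1]
        assert scan_tata("GG" + rc + "GG")

    def test_zero_threshold_always_false(self):
        assert not scan_tata("TATAAAAG", p_threshold=0)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            scan_tata("ACGT")

    def test_pvalue_matches_direct_enumeration(self):
        # score the consensus k-mer and verify its p-value equals the
        # fraction of k-mers (uniform background) scoring at least as high
        import itertools
        from promvol.classify import (_pwm_log_odds, _score_distribution,
                                      _pwm_pvalue, TATA_PWM_COUNTS, _BASE_INDEX)
        bg = np.full(4, 0.25)
        lo = _pwm_log_odds(TATA_PWM_COUNTS, bg)
        scores, probs = _score_distribution(lo, bg)
        kmer = "TATAAAAG"
        s = sum(lo[j, _BASE_INDEX[b]] for j, b in enumerate(kmer))
        brute = sum(
            1 for w in itertools.product("ACGT", repeat=8)
            if sum(lo[j, _BASE_INDEX[b]] for j, b in enumerate(w)) >= s - 1e-12
        ) / 4 ** 8
        assert _pwm_pvalue(s, scores, probs) == pytest.approx(brute, rel=1e-9)


class TestOverlapAnnotation:
    def test_one_bp_overlap_and_half_open_abutment(self):
        prom = pd.DataFrame([{"chrom": "chr1", "start": 100, "end": 200}])
        hit = pd.DataFrame([{"chrom": "chr1", "start": 199, "end": 300}])
        abut = pd.DataFrame([{"chrom": "chr1", "start": 200, "end": 300}])
        assert annotate_overlaps(prom, hit)[0]
        assert not annotate_overlaps(prom, abut)[0]
        assert not annotate_overlaps(prom, EMPTY).any()

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        ps = rng.integers(0, 5000, 100)
        prom = pd.DataFrame({"chrom": "chr1", "start": ps, "end": ps + 80})
        ts = rng.integers(0, 5000, 60)
        track = pd.DataFrame({"chrom": "chr1", "start": ts, "end": ts + 40})
        got = annotate_overlaps(prom, track)
        want = brute_force_overlap(prom["start"], prom["end"],
                                   track["start"], track["end"])
        assert np.array_equal(got, want)


class TestIsoformCount:
    def test_counts_and_flags(self, tmp_path):
        gm = pd.DataFrame([
            {"gene_id": "G1", "transcript_id": f"G1.T{i}", "chrom": "chr1",
             "start": 0, "end": 100, "strand": "+"} for i in range(3)
        ])
        path = tmp_path / "models.gtf"
        pio.write_gtf(gm, path)
        models = pio.read_gene_models(path)
        prom = pd.DataFrame([
            {"id": "a", "chrom": "chr1", "start": 0, "end": 10, "gene_id": "G1"},
            {"id": "b", "chrom": "chr1", "start": 0, "end": 10, "gene_id": None},
            {"id": "c", "chrom": "chr1", "start": 0, "end": 10, "gene_id": "GX"},
        ])
        out = assign_isoform_count(prom, models)
        assert out["isoform_count"].tolist() == [3, 0, 0]
        assert out["isoform_flagged"].tolist() == [False, True, True]

    def test_matches_groupby_oracle(self, small_dataset):
        out = assign_isoform_count(small_dataset.promoters,
                                   small_dataset.gene_models)
        oracle = small_dataset.gene_models.groupby("gene_id")["transcript_id"].nunique()
        for rec in out.itertuples(index=False):
            assert rec.isoform_count == oracle[rec.gene_id]
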