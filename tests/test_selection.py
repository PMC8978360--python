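import numpy as np
import pandas as pd
import pytest

from conftest import hypergeom_fisher_p
from promvol.selection import (bonferroni_confidence_level,
                               collect_region_counts, daf_test,
                               downsample_categories, per_population_daf,
                               spatial_enrichment)


def _anchors(n=20, spacing=10_000, width=200):
    starts = 5_000 + spacing * np.arange(n)
    return pd.DataFrame({"chrom": "chr1", "start": starts,
                         "end": starts + width, "strand": "+",
                         "tss": starts + width // 2})


class TestSpatialEnrichment:
    def test_uniform_events_give_flat_unit_profile(self):
        anchors = _anchors(10)
        rng = np.random.default_rng(0)
        events = rng.integers(0, 10_000 * 10 + 10_000, size=40_000)
        prof = spatial_enrichment(events, anchors, n_boot=0, seed=0)
        inner = np.abs(prof.offsets) <= 3_500
        assert np.abs(prof.rate[inner] - 1.0).max() < 0.35
        # flank mean is exactly 1 by construction
        flank = (np.abs(prof.offsets) >= 2_000) & (np.abs(prof.offsets) <= 4_000)
        assert prof.rate[flank].mean() == pytest.approx(1.0, abs=1e-9)

    def test_point_mass_peak_matches_windowed_count_oracle(self):
        anchors = _anchors(5)
        tss = anchors["tss"].to_numpy()
        # one event at every anchor's TSS + uniform flank events
        flank_ev = []
        for t in tss:
            flank_ev.extend(t - np.arange(2_000, 4_000, 50))
            flank_ev.extend(t + np.arange(2_000, 4_000, 50))
        events = np.concatenate([tss, np.array(flank_ev)])
        prof = spatial_enrichment(events, anchors, n_boot=0, seed=0)
        # oracle: naive per-window count at offset 0 over flank rate
        win_count = sum(np.abs(events - t) <= 125 for t in tss)
        rate0 = win_count.sum() if hasattr(win_count, "sum") else win_count
        naive_rate = sum(int(np.abs(events - t).min() == 0) for t in tss)
        peak = prof.rate[prof.offsets == 0][0]
        n_flank_events = len(flank_ev)
        flank_rate = n_flank_events / (len(anchors) * 2 * 2_001)
        point_rate = sum((np.abs(events - t) <= 124).sum() for t in tss) / (
            len(anchors) * 250)
        assert peak == pytest.approx(point_rate / flank_rate, rel=0.05)

    def test_no_bootstrap_means_no_ci(self):
        anchors = _anchors(3)
        offs = np.arange(-3_000, 3_000, 120)
        events = (anchors["tss"].to_numpy()[:, None] + offs[None, :]).ravel()
        prof = spatial_enrichment(events, anchors, n_boot=0)
        assert prof.ci_low is None and prof.ci_high is None

    def test_zero_flank_events_raises_naming_normalizer(self):
        anchors = _anchors(3)
        events = anchors["tss"].to_numpy()  # nothing in the flanks
        with pytest.raises(ValueError, match="flank"):
            spatial_enrichment(events, anchors, n_boot=0)

    def test_minus_strand_orientation_flips(self):
        anchors = _anchors(6).assign(strand="-")
        events = anchors["tss"].to_numpy() + 1_000  # genomic downstream
        events = np.concatenate([events] + [
            anchors["tss"].to_numpy() + d for d in range(2_000, 4_001, 100)
        ] + [anchors["tss"].to_numpy() - d for d in range(2_000, 4_001, 100)])
        prof = spatial_enrichment(events, anchors, n_boot=0)
        # on minus strands genomic +1000 is promoter-relative -1000
        assert prof.rate[prof.offsets == -1_000][0] > prof.rate[
            prof.offsets == 1_000][0]


class TestRegionCounts:
    def _polarized(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "pos", "vclass", "resolution",
                                         "daf_class_all"])
        return df

    def test_empty(self):
        prom = _anchors(2)
        assert collect_region_counts(self._polarized([]), prom) == (0, 0, 0, 0)

    def test_one_variant_per_cell(self):
        prom = _anchors(1)
        t = int(prom["tss"][0])
        rows = [
            ("chr1", t + 1, "SNP", "retained", "rare"),
            ("chr1", t + 2, "SNP", "retained", "common"),
            ("chr1", t - 3_000, "SNP", "retained", "rare"),
            ("chr1", t - 3_001, "SNP", "reversed", "common"),
            ("chr1", t - 3_002, "SNP", "excluded", "rare"),       # not counted
            ("chr1", t + 4, "SNP", "retained", "intermediate"),   # not counted
        ]
        assert collect_region_counts(self._polarized(rows), prom) == (1, 1, 1, 1)

    def test_matches_brute_force_membership(self, small_dataset):
        prom = small_dataset.promoters
        rng = np.random.default_rng(1)
        pos = rng.integers(1, prom["end"].max() + 5_000, size=10_000)
        klass = rng.choice(["rare", "common", "intermediate"], size=10_000)
        pol = pd.DataFrame({"chrom": "chr1", "pos": pos, "vclass": "SNP",
                            "resolution": "retained", "daf_class_all": klass})
        got = collect_region_counts(pol, prom, flank_side="upstream")
        # brute force: per-variant region membership scan
        rare = common = rare_f = common_f = 0
        for p0, k in zip(pos - 1, klass):
            in_prom = any(s - 50 <= p0 < e + 50
                          for s, e in zip(prom["start"], prom["end"]))
            in_flank = (not in_prom) and any(
                (t - 4_000 <= p0 <= t - 2_000) if s != "-" else
                (t + 2_000 <= p0 <= t + 4_000)
                for t, s in zip(prom["tss"], prom["strand"]))
            if in_prom and k == "rare":
                rare += 1
            elif in_prom and k == "common":
                common += 1
            elif in_flank and k == "rare":
                rare_f += 1
            elif in_flank and k == "common":
                common_f += 1
        assert got == (rare, common, rare_f, common_f)


class TestDAFTest:
    def test_identity_table(self):
        r = daf_test((10, 10, 10, 10))
        assert r.log2_or == pytest.approx(0.0, abs=1e-9)
        assert r.p == pytest.approx(1.0)

    def test_p_matches_hypergeometric_enumeration(self):
        r = daf_test((30, 10, 20, 20))
        want = hypergeom_fisher_p([[30, 10], [20, 20]])
        assert r.p == pytest.approx(want, rel=1e-9)
        assert r.sample_log2_or == pytest.approx(np.log2(3.0))
        assert r.log2_or > 0

    def test_zero_margin_degenerate(self):
        r = daf_test((0, 0, 5, 5))
        assert r.degenerate
        assert r.p == 1.0

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            daf_test((-1, 2, 3, 4))

    def test_bonferroni_ci_wider_than_nominal(self):
        nominal = daf_test((30, 10, 20, 20), n_tests=1)
        adjusted = daf_test((30, 10, 20, 20), n_tests=15)
        assert adjusted.ci_low < nominal.ci_low
        assert adjusted.ci_high > nominal.ci_high


def test_bonferroni_confidence_level():
    assert bonferroni_confidence_level(0.05, 1) == pytest.approx(95.0)
    assert round(bonferroni_confidence_level(0.05, 15), 1) == 99.7


class TestDownsample:
    def _prom(self):
        return pd.DataFrame({
            "id": [f"P{i}" for i in range(30)],
            "history": ["conserved"] * 20 + ["human_inserted"] * 10,
        })

    def test_identity_when_n_equals_size(self):
        prom = self._prom()
        out = downsample_categories(prom, 20, seed=1)
        assert (out[out["history"] == "conserved"].shape[0]) == 20

    def test_exact_subset_size_and_determinism(self):
        prom = self._prom()
        a = downsample_categories(prom, 5, seed=3)
        b = downsample_categories(prom, 5, seed=3)
        assert (a["history"].value_counts() == 5).all()
        assert a["id"].tolist() == b["id"].tolist()
        c = downsample_categories(prom, 5, seed=4)
        assert a["id"].tolist() != c["id"].tolist()

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            downsample_categories(self._prom(), -1)


class TestPerPopulation:
    def test_bookkeeping(self, small_dataset, alignment_index):
        from promvol.polarize import polarize_variants, polarized_to_frame

        pol, _ = polarize_variants(small_dataset.variants, alignment_index)
        frame = polarized_to_frame(pol)
        prom = small_dataset.promoters
        res = per_population_daf(frame, prom, populations=("AFR",),
                                 categories=["conserved"], vclasses=("SNP",))
        assert len(res) == 1
        assert res[0].n_tests == 1
        res5 = per_population_daf(frame, prom,
                                  categories=["conserved"], vclasses=("SNP",))
        assert len(res5) == 5
        assert all(r.n_tests == 5 for r in res5)

    def test_population_identical_to_combined(self):
        # a population whose AF equals the combined panel gives the same test
        rows = []
        rng = np.random.default_rng(0)
        prom = _anchors(4)
        for i, t in enumerate(prom["tss"]):
            for off in (-3000, -2500, 0, 10):
                k = rng.choice(["rare", "common"])
                rows.append({"chrom": "chr1", "pos": t + off, "vclass": "SNP",
                             "resolution": "retained", "daf_class_all": k,
                             "daf_class_eur": k})
        pol = pd.DataFrame(rows)
        a = collect_region_counts(pol, prom, population="all")
        b = collect_region_counts(pol, prom, population="eur")
        assert a == b
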