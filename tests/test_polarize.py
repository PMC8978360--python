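import itertools

import numpy as np
import pandas as pd
import pytest

from promvol.alignment import AlignmentBlock, AlignmentIndex, SpeciesRow
from promvol.polarize import (AncestralWindow, classify_daf, filter_variants,
                              is_transversion, polarize_variants,
                              project_window, resolve_indel, resolve_snp)

AF = {"ALL": 0.3, "AFR": 0.25}


def _window(human, anc, vcol=2):
    return AncestralWindow(human_seq=human, ancestral_seq=anc,
                           has_gap_in_window=("-" in human) or ("-" in anc),
                           source="ancestral", variant_column=vcol)


class TestResolveSNP:
    def test_ancestral_equals_ref_retained(self):
        v = resolve_snp("chr1", 100, "A", "G", _window("CCACC", "CCACC"), AF)
        assert v.resolution == "retained"
        assert v.ancestral_allele == "A"
        assert v.daf["ALL"] == pytest.approx(0.3)   # derived allele is ALT

    def test_ancestral_equals_alt_reversed(self):
        v = resolve_snp("chr1", 100, "A", "G", _window("CCACC", "CCGCC"), AF)
        assert v.resolution == "reversed"
        assert v.ancestral_allele == "G"
        assert v.daf["ALL"] == pytest.approx(0.7)   # daf = 1 - alt AF

    def test_third_base_excluded(self):
        v = resolve_snp("chr1", 100, "A", "G", _window("CCACC", "CCCCC"), AF)
        assert v.resolution == "excluded"
        assert v.exclusion_reason == "unresolvable"
        assert not v.daf

    def test_gap_in_window_excluded(self):
        v = resolve_snp("chr1", 100, "A", "G", _window("CCACC", "CC-CC"), AF)
        assert v.resolution == "excluded"
        assert v.exclusion_reason == "gapped_window"

    def test_unaligned_excluded(self):
        v = resolve_snp("chr1", 100, "A", "G", None, AF)
        assert v.exclusion_reason == "unaligned"


class TestResolveIndel:
    # annotated insertion: ref="AT", alt="ATGG"
    def test_ancestral_matches_ref_length_retained(self):
        # window = ref span + 2 bp each side -> 6 ungapped columns
        w = _window("CCATCC", "CCATCC")
        v = resolve_indel("chr1", 100, "AT", "ATGG", w, AF)
        assert v.resolution == "retained"
        assert v.vclass == "insertion"
        assert v.daf["ALL"] == pytest.approx(0.3)

    def test_ancestral_matches_alt_length_reversed(self):
        # manual gap-strip oracle: ancestral row has the 2 extra bases that
        # the human reference lacks -> stripped length 8 = len(alt) + 4,
        # so the annotated insertion is really a human-lineage deletion
        w = _window("CCAT--CC", "CCATGGCC")
        anc_len = len(w.ancestral_seq.replace("-", ""))
        assert anc_len == len("ATGG") + 4
        v = resolve_indel("chr1", 100, "AT", "ATGG", w, AF)
        assert v.resolution == "reversed"
        assert v.ancestral_allele == "ATGG"
        assert v.daf["ALL"] == pytest.approx(0.7)

    def test_length_matching_neither_excluded(self):
        w = _window("CCAT---CC", "CCATGGGCC")
        v = resolve_indel("chr1", 100, "AT", "ATGG", w, AF)
        assert v.resolution == "excluded"
        assert v.exclusion_reason == "unresolvable"

    def test_deletion_reversed(self):
        # annotated deletion ref="ATG", alt="A"; ancestral matches alt length
        w = _window("CCATGCC", "CCA--CC")
        v = resolve_indel("chr1", 100, "ATG", "A", w, AF)
        assert v.resolution == "reversed"
        assert v.vclass == "deletion"

    def test_unaligned_excluded(self):
        v = resolve_indel("chr1", 100, "AT", "ATGG", None, AF)
        assert v.exclusion_reason == "unaligned"


class TestDAFClass:
    @pytest.mark.parametrize("daf,expected", [
        (0.010, "rare"), (0.0149, "rare"), (0.015, "intermediate"),
        (0.05, "intermediate"), (0.0501, "common"), (0.10, "common"),
        (0.0, "rare"), (1.0, "common"),
    ])
    def test_thresholds(self, daf, expected):
        assert classify_daf(daf) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify_daf(1.5)
        with pytest.raises(ValueError):
            classify_daf(-0.1)


class TestTransversion:
    def test_enumeration(self):
        pairs = [(r, a) for r, a in itertools.permutations("ACGT", 2)]
        tv = [p for p in pairs if is_transversion(*p)]
        assert len(pairs) == 12
        assert len(tv) == 8
        assert not is_transversion("A", "G")
        assert is_transversion("A", "C")

    def test_rejects_non_bases(self):
        with pytest.raises(ValueError):
            is_transversion("A", "N")


class TestFilterVariants:
    def test_multi_position_and_conservation(self):
        df = pd.DataFrame({
            "chrom": ["chr1"] * 4,
            "pos": [10, 10, 20, 30],
            "id": ["a", "b", "c", "d"],
            "ref": ["A", "A", "C", "G"],
            "alt": ["G", "T", "T", "A"],
        })
        kept, log = filter_variants(df)
        assert len(kept) + len(log) == 4
        assert kept["pos"].tolist() == [20, 30]
        assert set(log["exclusion_reason"]) == {"multi_allelic"}

    def test_multi_mapping_removed_first(self):
        df = pd.DataFrame({
            "chrom": ["chr1", "chr2"], "pos": [10, 99],
            "id": ["dup", "dup"], "ref": ["A", "C"], "alt": ["G", "T"],
        })
        kept, log = filter_variants(df)
        assert len(kept) == 0
        assert (log["exclusion_reason"] == "multi_mapping").all()

    def test_unique_records_kept(self):
        df = pd.DataFrame({"chrom": ["chr1"], "pos": [5], "id": ["x"],
                           "ref": ["A"], "alt": ["T"]})
        kept, log = filter_variants(df)
        assert len(kept) == 1 and len(log) == 0


class TestProjectWindow:
    def _index(self):
        rows = {"human": SpeciesRow(src="human.chr1", start=100, text="AACGTACGTT"),
                "ancestral": SpeciesRow(src="ancestral.chr1", start=0,
                                        text="AACGTACGTT")}
        return AlignmentIndex([AlignmentBlock(rows=rows)])

    def test_inside_block_returns_window(self):
        w = project_window("chr1", 105, "A", self._index())
        assert w is not None
        assert len(w.human_seq) == 5
        assert not w.has_gap_in_window

    def test_outside_blocks_returns_none(self):
        assert project_window("chr1", 500, "A", self._index()) is None

    def test_unknown_chromosome_returns_none(self):
        assert project_window("chrZ", 105, "A", self._index()) is None

    def test_gap_in_ancestral_row_flagged(self):
        rows = {"human": SpeciesRow(src="human.chr1", start=100, text="AACGTACGTT"),
                "ancestral": SpeciesRow(src="ancestral.chr1", start=0,
                                        text="AACG-ACGTT")}
        idx = AlignmentIndex([AlignmentBlock(rows=rows)])
        w = project_window("chr1", 105, "A", idx)
        assert w.has_gap_in_window


class TestPolarizeInvariants:
    def test_label_symmetry_under_allele_swap(self):
        # swapping ref/alt with AF -> 1-AF leaves daf and class unchanged
        w_fwd = _window("CCACC", "CCACC")
        v1 = resolve_snp("chr1", 100, "A", "G", w_fwd, {"ALL": 0.3})
        v2 = resolve_snp("chr1", 100, "G", "A", w_fwd, {"ALL": 0.7})
        assert v1.daf["ALL"] == pytest.approx(v2.daf["ALL"])
        assert v1.daf_class == v2.daf_class

    def test_daf_complement_invariant(self):
        for af in (0.01, 0.3, 0.99):
            ret = resolve_snp("c", 9, "A", "G", _window("TTATT", "TTATT"),
                              {"ALL": af})
            rev = resolve_snp("c", 9, "A", "G", _window("TTATT", "TTGTT"),
                              {"ALL": af})
            assert ret.daf["ALL"] + (1 - af) == pytest.approx(1.0)
            assert rev.daf["ALL"] == pytest.approx(1.0 - af)

    def test_conservation_on_synthetic_data(self, small_dataset, alignment_index):
        from promvol import io as pio
        from promvol.polarize import polarized_to_frame

        variants = small_dataset.variants
        pol, log = polarize_variants(variants, alignment_index)
        frame = polarized_to_frame(pol)
        assert len(frame) + len(log) == len(variants)
        counts = frame["resolution"].value_counts()
        assert counts.sum() == len(frame)
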