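"""Variant calling, tiers, SNP masking, filtering and table round trips."""

import numpy as np
import pandas as pd
import pysam
import pytest

from duplexpipe import varcall as vc
from duplexpipe.consensus import Pileup


def _pileup_with(model, entries):
    """entries: (position, alt_code, alt_count, coverage); coverage is shared
    by all entries at one position, the reference takes the remainder."""
    n = len(model)
    pile = Pileup(np.zeros(n, dtype=np.int64), np.zeros((4, n), dtype=np.int64))
    for pos, alt, k, _ in entries:
        pile.counts[alt, pos] += k
    for pos, _, _, cov in entries:
        ref = model.codes[pos]
        alt_total = pile.counts[:, pos].sum() - pile.counts[ref, pos]
        pile.counts[ref, pos] = cov - alt_total
        pile.coverage[pos] = cov
    return pile


def _call_row(lib="L1", pos=100, ref="C", alt="T", vaf=1e-4, cov=10000,
              tier=vc.TIER1, category="missense", snp=False):
    return {
        "library_id": lib, "position": pos, "ref": ref, "alt": alt,
        "alt_count": max(1, int(round(vaf * cov))), "dcs_coverage": cov, "vaf": vaf,
        "tier": tier, "category": category, "flag_snp": snp,
    }


class TestCallVariants:
    def test_two_alts_at_one_position_give_two_calls(self, model):
        pos = 50
        alts = [c for c in range(4) if c != model.codes[pos]][:2]
        pile = _pileup_with(model, [(pos, alts[0], 3, 30000), (pos, alts[1], 2, 30000)])
        calls = vc.call_variants(pile, model, "L1")
        assert len(calls) == 2
        assert calls["vaf"].iloc[0] == pytest.approx(1e-4)
        assert set(calls["alt"]) == {"ACGT"[a] for a in alts}

    def test_zero_alt_positions_yield_no_calls(self, model):
        pile = _pileup_with(model, [(10, model.codes[10], 0, 500)])
        pile.counts[model.codes[10], 10] = 500
        pile.coverage[10] = 500
        assert vc.call_variants(pile, model).empty


class TestAssignTier:
    def test_strong_evidence_on_both_strands_is_tier1(self):
        assert vc.assign_tier([(5, 5, 1.0, 1.0)]) == vc.TIER1

    def test_single_read_strand_with_full_agreement_is_tier2(self):
        assert vc.assign_tier([(1, 5, 1.0, 1.0)]) == vc.TIER2

    def test_support_below_tier2_floor_is_lower(self):
        assert vc.assign_tier([(5, 5, 0.9, 0.6)]) == vc.TIER_LOWER

    def test_every_supporting_dcs_must_qualify(self):
        assert vc.assign_tier([(5, 5, 1.0, 1.0), (1, 1, 1.0, 1.0)]) == vc.TIER2

    def test_missing_evidence_is_an_error(self):
        with pytest.raises(ValueError, match="evidence"):
            vc.assign_tier([])

    def test_threshold_table(self):
        thr = vc.TierThresholds(tier1_min_reads=3, tier1_min_fraction=0.75)
        assert vc.assign_tier([(3, 3, 0.75, 0.75)], thr) == vc.TIER1
        assert vc.assign_tier([(3, 3, 0.75, 0.74)], thr) == vc.TIER_LOWER


class TestMaskSnps:
    META = [
        vc.LibraryMeta("L1", "poolA", "younger", "Up"),
        vc.LibraryMeta("L2", "poolA", "younger", "Up"),
        vc.LibraryMeta("L3", "poolA", "younger", "Up"),
        vc.LibraryMeta("L4", "poolB", "older", "Up"),
    ]

    def test_variant_in_all_sharing_libraries_at_high_vaf_is_snp(self):
        calls = pd.DataFrame([_call_row(lib=f"L{i}", vaf=0.10) for i in (1, 2, 3)])
        out = vc.mask_snps(calls, self.META)
        assert out["flag_snp"].all()

    def test_two_of_three_sharing_libraries_is_not_snp(self):
        calls = pd.DataFrame([_call_row(lib=f"L{i}", vaf=0.10) for i in (1, 2)])
        out = vc.mask_snps(calls, self.META)
        assert not out["flag_snp"].any()

    def test_ultra_rare_vaf_never_snp(self):
        calls = pd.DataFrame([_call_row(lib=f"L{i}", vaf=1e-4) for i in (1, 2, 3)])
        assert not vc.mask_snps(calls, self.META)["flag_snp"].any()

    def test_other_pool_unaffected(self):
        calls = pd.DataFrame(
            [_call_row(lib=f"L{i}", vaf=0.10) for i in (1, 2, 3)] + [_call_row(lib="L4", vaf=1e-4)]
        )
        out = vc.mask_snps(calls, self.META)
        assert out[out["library_id"] == "L4"]["flag_snp"].eq(False).all()
        assert out[out["library_id"] != "L4"]["flag_snp"].all()

    def test_unknown_library_rejected(self):
        calls = pd.DataFrame([_call_row(lib="L9")])
        with pytest.raises(KeyError, match="L9"):
            vc.mask_snps(calls, self.META)


class TestFilterVariants:
    def test_coverage_below_threshold_removed(self):
        calls = pd.DataFrame([_call_row(cov=999), _call_row(pos=101, cov=1000)])
        out = vc.filter_variants(calls)
        assert list(out["position"]) == [101]

    def test_tier2_needs_two_detections(self):
        once = pd.DataFrame([_call_row(tier=vc.TIER2)])
        assert vc.filter_variants(once).empty
        twice = pd.DataFrame(
            [_call_row(tier=vc.TIER2, lib="L1"), _call_row(tier=vc.TIER2, lib="L2")]
        )
        assert len(vc.filter_variants(twice)) == 2

    def test_detection_count_invariant_to_library_order(self):
        rows = [_call_row(tier=vc.TIER2, lib="L1"), _call_row(tier=vc.TIER2, lib="L2")]
        a = vc.filter_variants(pd.DataFrame(rows))
        b = vc.filter_variants(pd.DataFrame(rows[::-1]))
        assert len(a) == len(b) == 2

    def test_intronic_and_snp_removed(self):
        calls = pd.DataFrame(
            [
                _call_row(category="intronic"),
                _call_row(pos=101, snp=True),
                _call_row(pos=102, category="splice_region"),
                _call_row(pos=103),
            ]
        )
        out = vc.filter_variants(calls)
        # splice-region calls are non-intronic and survive alongside exonic ones
        assert sorted(out["position"]) == [102, 103]

    def test_lower_tier_removed(self):
        calls = pd.DataFrame([_call_row(tier=vc.TIER_LOWER)])
        assert vc.filter_variants(calls).empty


class TestPersistence:
    def test_tsv_round_trip(self, tmp_path):
        calls = pd.DataFrame([_call_row(), _call_row(pos=101, alt="G")])
        path = tmp_path / "t.tsv"
        vc.write_variant_table(calls, path)
        back = vc.read_variant_table(path)
        pd.testing.assert_frame_equal(back, calls)

    def test_tsv_positions_are_one_based_on_disk(self, tmp_path):
        calls = pd.DataFrame([_call_row(pos=99)])
        vc.write_variant_table(calls, tmp_path / "t.tsv")
        on_disk = pd.read_csv(tmp_path / "t.tsv", sep="\t")
        assert on_disk["position"].iloc[0] == 100

    def test_empty_table_round_trips(self, tmp_path):
        calls = pd.DataFrame(columns=vc.CALL_COLUMNS)
        vc.write_variant_table(calls, tmp_path / "t.tsv")
        assert vc.read_variant_table(tmp_path / "t.tsv").empty

    def test_vcf_output_readable_by_pysam(self, model, tmp_path):
        pos = 50
        ref = model.sequence[pos]
        alts = [b for b in "ACGT" if b != ref][:2]
        calls = pd.DataFrame(
            [
                {**_call_row(pos=pos, ref=ref, alt=alts[0]), "hgvs_c": "c.1A>T", "hgvs_p": "p.X1Y", "domain": "TK"},
                {**_call_row(pos=pos, ref=ref, alt=alts[1]), "hgvs_c": "", "hgvs_p": "", "domain": None},
            ]
        )
        path = tmp_path / "v.vcf"
        vc.write_vcf(calls, model, path)
        recs = list(pysam.VariantFile(str(path)))
        assert len(recs) == 2  # multi-allelic site -> two records
        assert recs[0].pos == pos + 1
        assert recs[0].info["DP"] == 10000
        assert recs[0].info["TIER"] == vc.TIER1

    def test_vcf_empty_set_is_valid_header_only(self, model, tmp_path):
        path = tmp_path / "e.vcf"
        vc.write_vcf(pd.DataFrame(columns=vc.CALL_COLUMNS), model, path)
        assert list(pysam.VariantFile(str(path))) == []
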