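"""Consensus building: scalar contracts, brute-force oracle, batch parity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duplexpipe import consensus as cns
from duplexpipe import duplexsim as sim
from duplexpipe._seqcodes import revcomp_str


class TestGroupFamilies:
    def test_opposite_tag_orders_are_one_family_two_strands(self):
        pairs = [
            cns.TaggedReadPair("AAAA", "CCCC", "ACGT"),
            cns.TaggedReadPair("CCCC", "AAAA", "ACGT"),
        ]
        fams, discarded = cns.group_families(pairs)
        assert discarded == 0
        assert len(fams) == 1
        assert fams[0].family_key == ("AAAA", "CCCC")
        assert len(fams[0].strand_a_reads) == 1
        assert len(fams[0].strand_b_reads) == 1

    def test_unique_tags_give_singleton_families(self):
        pairs = [cns.TaggedReadPair(f"AA{b}A", "CCCC", "ACGT") for b in "CGT"]
        fams, _ = cns.group_families(pairs)
        assert len(fams) == 3
        assert all(len(f.strand_a_reads) + len(f.strand_b_reads) == 1 for f in fams)

    def test_tag_with_n_discarded_and_counted(self):
        pairs = [cns.TaggedReadPair("ANAA", "CCCC", "ACGT")]
        fams, discarded = cns.group_families(pairs)
        assert fams == [] and discarded == 1

    def test_empty_input(self):
        assert cns.group_families([]) == ([], 0)


class TestBuildSscs:
    def test_majority_base_wins_with_support_fraction(self):
        reads = ["ACGT", "ACGT", "ACGT", "ACGT", "ACTT"]  # 4/5 G at pos 2
        s = cns.build_sscs(reads, min_family_size=3, majority=0.7)
        assert s.sequence == "ACGT"
        assert s.support[2] == pytest.approx(0.8)

    def test_family_below_min_size_rejected(self):
        assert cns.build_sscs(["ACGT", "ACGT"], min_family_size=3) is None

    def test_two_one_split_below_majority_is_n(self):
        s = cns.build_sscs(["AAAA", "AAAA", "ATAA"], min_family_size=3, majority=0.7)
        assert s.sequence == "ANAA"  # 2/3 = 0.667 < 0.7

    def test_tie_at_exact_threshold_is_n(self):
        reads = ["A"] * 7 + ["C"] * 3  # support exactly 0.7
        s = cns.build_sscs(reads, min_family_size=3, majority=0.7)
        assert s.sequence == "N"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cns.build_sscs(["ACGT", "ACG", "ACGT"])

    @given(
        st.lists(
            st.lists(st.sampled_from("ACGTN"), min_size=6, max_size=6),
            min_size=3,
            max_size=12,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_per_position_tally_oracle(self, fam):
        """Consensus equals an independent per-position counting oracle."""
        reads = ["".join(r) for r in fam]
        s = cns.build_sscs(reads, min_family_size=3, majority=0.7)
        for i, called in enumerate(s.sequence):
            column = [r[i] for r in reads if r[i] != "N"]
            if not column:
                assert called == "N"
                continue
            best = max("ACGT", key=column.count)
            if column.count(best) > 0.7 * len(column):
                assert called == best
            else:
                assert called == "N"


class TestBuildDcs:
    def _sscs(self, seq, key=("A", "B"), strand="a"):
        return cns.SSCS(seq, 3, (1.0,) * len(seq), key, strand)

    def test_agreement_on_alt_is_kept(self):
        d = cns.build_dcs(self._sscs("ACTT"), self._sscs("ACTT", strand="b"))
        assert d.sequence == "ACTT"

    def test_single_strand_alt_becomes_n(self):
        # a lesion: alternate base on one strand only
        d = cns.build_dcs(self._sscs("ACTT"), self._sscs("ACGT", strand="b"))
        assert d.sequence == "ACNT"

    def test_identical_reference_pair_gives_reference(self):
        d = cns.build_dcs(self._sscs("ACGT"), self._sscs("ACGT", strand="b"))
        assert d.sequence == "ACGT"

    def test_n_propagates(self):
        d = cns.build_dcs(self._sscs("ANGT"), self._sscs("ACGT", strand="b"))
        assert d.sequence == "ANGT"

    def test_mismatched_family_keys_rejected(self):
        with pytest.raises(ValueError, match="family keys"):
            cns.build_dcs(self._sscs("ACGT", key=("A", "B")), self._sscs("ACGT", key=("A", "C")))


class TestPileup:
    def test_reference_dcs_only(self, model, layout):
        s, e = layout.subregion("Up1")
        ref = model.sequence[s:e]
        pile = cns.pileup([cns.DCS(ref, subregion="Up1")] * 10, model, layout)
        assert (pile.coverage[s:e] == 10).all()
        assert pile.alt_counts(model.codes).sum() == 0

    def test_alt_and_n_bookkeeping(self, model, layout):
        s, e = layout.subregion("Up1")
        ref = model.sequence[s:e]
        alt_base = "A" if ref[0] != "A" else "C"
        with_alt = alt_base + ref[1:]
        with_n = "N" + ref[1:]
        pile = cns.pileup(
            [cns.DCS(ref, subregion="Up1")] * 8
            + [cns.DCS(with_alt, subregion="Up1"), cns.DCS(with_n, subregion="Up1")],
            model,
            layout,
        )
        assert pile.coverage[s] == 9  # the N row drops out of coverage
        assert pile.counts[:, s].sum() == pile.coverage[s]
        assert pile.alt_counts(model.codes)[s] == 1

    def test_unknown_subregion_rejected(self, model, layout):
        with pytest.raises(ValueError, match="not in layout"):
            cns.pileup([cns.DCS("ACGT", subregion="nope")], model, layout)


@pytest.fixture(scope="module")
def small_library(gene, tmp_path_factory):
    model, layout = gene
    cfg = sim.SimConfig(
        seed=42,
        n_molecules=40,
        subregions=("Up2",),
        seq_error_rate=0.01,
        damage_rate_deam=0.002,
        damage_rate_oxoG=0.001,
        pcr_error_rate=1e-4,
    )
    lib = sim.simulate_library(cfg, model, layout, tmp_path_factory.mktemp("fq"), "s")
    return model, layout, lib


class TestBatchAgainstScalar:
    """The vectorised FASTQ path must reproduce the scalar object path."""

    def _scalar_dcs(self, model, layout, lib, params):
        """Re-derive every DCS by parsing the FASTQ with the scalar API."""
        from Bio import SeqIO

        s, e = layout.subregion("Up2")
        length = e - s
        pairs = []
        r1 = list(SeqIO.parse(str(lib.r1_path), "fastq"))
        r2 = list(SeqIO.parse(str(lib.r2_path), "fastq"))
        for a, b in zip(r1, r2):
            _, sub, ori, _ = a.id.split(":")
            t1, seq1 = str(a.seq)[:12], str(a.seq)[12:]
            t2, seq2 = str(b.seq)[:12], str(b.seq)[12:]
            if ori == "FR":
                m1, m2 = seq1, revcomp_str(seq2)
            else:
                m1, m2 = revcomp_str(seq1), seq2
            merged = "".join(x if x == y else "N" for x, y in zip(m1, m2))
            pairs.append(cns.TaggedReadPair(t1, t2, merged, sub))
        fams, _ = cns.group_families(pairs)
        out = {}
        for fam in fams:
            sa = cns.build_sscs(fam.strand_a_reads, params.min_family_size, params.majority,
                                fam.family_key, "a")
            sb = cns.build_sscs(fam.strand_b_reads, params.min_family_size, params.majority,
                                fam.family_key, "b")
            if sa and sb:
                out["".join(fam.family_key)] = cns.build_dcs(sa, sb).sequence
        assert length  # sanity: subregion resolved
        return out

    def test_every_duplex_consensus_matches(self, small_library):
        model, layout, lib = small_library
        params = cns.ConsensusParams()
        lc = cns.consensus_library(lib.r1_path, lib.r2_path, model, layout, params, "s")
        sub = lc.subregions["Up2"]
        got = {
            sub.family_keys[i].decode(): "".join("ACGTN"[c] for c in sub.dcs[i])
            for i in range(sub.dcs.shape[0])
        }
        expected = self._scalar_dcs(model, layout, lib, params)
        assert got == expected

    def test_pileup_counts_sum_to_coverage(self, small_library):
        model, layout, lib = small_library
        lc = cns.consensus_library(lib.r1_path, lib.r2_path, model, layout, library_id="s")
        pile = cns.dcs_pileup(lc, model)
        assert (pile.counts.sum(axis=0) == pile.coverage).all()

    def test_family_sizes_bounded_by_truth(self, small_library):
        model, layout, lib = small_library
        lc = cns.consensus_library(lib.r1_path, lib.r2_path, model, layout, library_id="s")
        sub = lc.subregions["Up2"]
        truth_sizes = lib.truth.family_sizes["Up2"]
        assert sub.fam_sizes.sum() <= truth_sizes.sum()
        assert (sub.fam_sizes >= cns.ConsensusParams().min_family_size).all()
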