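"""Mutational spectra: folding, contexts, normalisation, cosine bootstrap."""

import numpy as np
import pandas as pd
import pytest

from duplexpipe import spectra as spc
from duplexpipe.freqstats import LibrarySummary
from duplexpipe.refmodel import ReferenceModel


def _variants(rows):
    return pd.DataFrame(rows, columns=["position", "ref", "alt"])


class TestFolding:
    def test_single_ct_variant_vector(self, model):
        pos = int(np.flatnonzero(model.codes == 1)[10])  # a C site
        spec = spc.spectrum(_variants([(pos, "C", "T")]), model, 6)
        assert spec.labels == spc.CLASSES6
        assert list(spec.counts) == [0, 0, 1, 0, 0, 0]

    def test_purine_reference_folds_to_pyrimidine_class(self):
        assert spc.class6_index("G", "A") == spc.class6_index("C", "T")
        assert spc.class6_index("A", "C") == spc.class6_index("T", "G")

    @pytest.mark.parametrize("ref,alt", [(r, a) for r in "ACGT" for a in "ACGT" if r != a])
    def test_folding_is_an_involution(self, ref, alt):
        from duplexpipe._seqcodes import revcomp_str

        assert spc.class6_index(ref, alt) == spc.class6_index(revcomp_str(ref), revcomp_str(alt))

    def test_context_folds_with_the_strand(self):
        # T[C>T]G read on the other strand is C[G>A]A
        assert spc.context96_index("C", "T", "T", "G") == spc.context96_index("G", "A", "C", "A")


class TestSpectrum:
    def test_cpg_transition_lands_in_tcg_bin(self):
        m = ReferenceModel("toy", "ATCGA", exons=[(0, 5)])
        spec = spc.spectrum(_variants([(2, "C", "T")]), m, 96)
        lab = spec.labels[int(np.flatnonzero(spec.counts)[0])]
        assert lab == "T[C>T]G"
        assert spc.cpg_transition_count(spec) == 1

    def test_96_marginalizes_to_6_exactly(self, model):
        rng = np.random.default_rng(5)
        rows = []
        for pos in rng.integers(1, len(model) - 1, size=40):
            ref = model.sequence[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append((int(pos), ref, alt))
        v = _variants(rows)
        s96 = spc.spectrum(v, model, 96)
        s6 = spc.spectrum(v, model, 6)
        folded = spc.marginalize96(s96)
        assert (folded.counts == s6.counts).all()
        assert (folded.opportunities <= s6.opportunities).all()  # edges lack context

    def test_edge_position_without_context_rejected(self):
        m = ReferenceModel("toy", "CATG", exons=[(0, 4)])
        with pytest.raises(ValueError, match="context"):
            spc.spectrum(_variants([(0, "C", "T")]), m, 96)

    def test_opportunities_count_reference_bases(self, model):
        spec = spc.spectrum(_variants([]), model, 6)
        n_cg = int(((model.codes == 1) | (model.codes == 2)).sum())
        assert spec.opportunities[0] == n_cg  # C>A class opportunity = C+G sites


class TestStrandSpectrum:
    def test_pyrimidine_reference_is_untranscribed_strand(self, model):
        df = spc.strand_spectrum(_variants([(10, "C", "T")]) if model.sequence[10] == "C"
                                 else _variants([(int(np.flatnonzero(model.codes == 1)[0]), "C", "T")]),
                                 model)
        assert df.loc["C>T", "untranscribed"] == 1
        assert df["transcribed"].sum() == 0

    def test_purine_reference_is_transcribed_strand(self, model):
        pos = int(np.flatnonzero(model.codes == 2)[0])  # a G site
        df = spc.strand_spectrum(_variants([(pos, "G", "A")]), model)
        assert df.loc["C>T", "transcribed"] == 1

    def test_empty_set_all_zero(self, model):
        assert spc.strand_spectrum(_variants([]), model).to_numpy().sum() == 0


class TestNormalizedFrequency:
    def test_toy_arithmetic_oracle(self):
        # 1 C>T variant, 100 C sites in a 400 bp region, one library at
        # coverage 10,000: 1 / ((100/400) * 10000 * 400) = 1e-6
        spec = spc.SpectrumMatrix(
            spc.CLASSES6,
            np.array([0, 0, 1, 0, 0, 0]),
            np.array([100, 100, 100, 300, 300, 300]),
            400,
        )
        freqs = spc.normalized_frequency_spectrum(spec, [LibrarySummary("L", 1, 10000.0, 400)])
        assert freqs[2] == pytest.approx(1e-6)

    def test_doubling_coverage_halves_frequencies(self, model):
        v = _variants([(int(np.flatnonzero(model.codes == 1)[0]), "C", "T")])
        spec = spc.spectrum(v, model, 6)
        f1 = spc.normalized_frequency_spectrum(spec, [LibrarySummary("L", 1, 10000.0, 4405)])
        f2 = spc.normalized_frequency_spectrum(spec, [LibrarySummary("L", 1, 20000.0, 4405)])
        assert f2[2] == pytest.approx(f1[2] / 2)

    def test_count_without_opportunity_rejected(self):
        spec = spc.SpectrumMatrix(spc.CLASSES6, np.array([0, 0, 1, 0, 0, 0]), np.zeros(6, dtype=int), 400)
        with pytest.raises(ValueError, match="zero opportunity"):
            spc.normalized_frequency_spectrum(spec, [LibrarySummary("L", 1, 1000.0, 400)])

    def test_weighted_class_frequencies_reconstruct_total_count(self, model):
        rng = np.random.default_rng(9)
        rows = []
        for pos in rng.integers(1, len(model) - 1, size=30):
            ref = model.sequence[pos]
            rows.append((int(pos), ref, rng.choice([b for b in "ACGT" if b != ref])))
        spec = spc.spectrum(_variants(rows), model, 6)
        summaries = [LibrarySummary("L", 30, 12000.0, 4405)]
        freqs = spc.normalized_frequency_spectrum(spec, summaries)
        exposure = summaries[0].exposure
        total = sum(
            f * (o / spec.region_size) * exposure for f, o in zip(freqs, spec.opportunities)
        )
        assert total == pytest.approx(spec.counts.sum())


class TestCosine:
    def test_identical_spectra(self):
        a = np.array([1, 2, 3, 0, 0, 1.0])
        assert spc.cosine_similarity(a, a) == pytest.approx(1.0)

    def test_disjoint_support(self):
        assert spc.cosine_similarity(np.array([1, 0, 0.0]), np.array([0, 1, 1.0])) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero spectrum"):
            spc.cosine_similarity(np.zeros(6), np.ones(6))


class TestBootstrap:
    REF = np.array([30, 5, 50, 2, 8, 5.0])

    def test_exact_iteration_count_and_range(self):
        boot = spc.bootstrap_cosine_reference(self.REF, n=20, iterations=1000, seed=1)
        assert boot.draws.shape == (1000,)
        assert ((boot.draws >= 0) & (boot.draws <= 1)).all()

    def test_seed_reproducible(self):
        a = spc.bootstrap_cosine_reference(self.REF, 20, 200, seed=7).draws
        b = spc.bootstrap_cosine_reference(self.REF, 20, 200, seed=7).draws
        assert (a == b).all()

    def test_concentrated_reference_always_cosine_one(self):
        ref = np.array([0, 0, 10, 0, 0, 0.0])
        boot = spc.bootstrap_cosine_reference(ref, 5, 100, seed=0)
        assert np.allclose(boot.draws, 1.0)

    def test_mean_cosine_increases_with_sample_size(self):
        means = [
            spc.bootstrap_cosine_reference(self.REF, n, 400, seed=3).draws.mean()
            for n in (10, 100, 1000)
        ]
        assert means[0] < means[1] < means[2]
        assert means[2] > 0.99  # converges to 1 as n grows

    def test_observed_cosine_attached_by_query_helper(self):
        boot = spc.cosine_with_bootstrap(self.REF * 2, self.REF, iterations=50, seed=0)
        assert boot.observed == pytest.approx(1.0)
        assert boot.n == int(self.REF.sum() * 2)

    def test_resample_both_mode_runs(self):
        boot = spc.bootstrap_cosine_reference(self.REF, 50, 100, seed=2, resample_both=True)
        assert boot.draws.shape == (100,)

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            spc.bootstrap_cosine_reference(self.REF, 0)
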