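import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnmkit import postzygotic as pz
from dnmkit.errors import FilterError


def pz_record(**overrides):
    base = {
        "vaf_exome": 0.2,
        "alt_reads_proband": 10,
        "alt_reads_father": 0,
        "alt_reads_mother": 0,
        "depth_father": 50,
        "depth_mother": 50,
        "strand_support": True,
        "tlod": 20.0,
        "in_cnv_region": False,
    }
    base.update(overrides)
    return base


class TestPzCandidateFilter:
    @pytest.mark.parametrize(
        "override,kept",
        [
            ({}, True),
            ({"vaf_exome": 0.35}, False),  # strict <
            ({"vaf_exome": 0.34}, True),
            ({"alt_reads_proband": 4}, False),
            ({"alt_reads_proband": 5}, True),
            ({"alt_reads_father": 2}, False),
            ({"alt_reads_mother": 1}, True),
            ({"depth_father": 9}, False),
            ({"depth_mother": 10}, True),
            ({"tlod": 4.9}, False),
            ({"tlod": 5.0}, True),
            ({"strand_support": False}, False),
            ({"in_cnv_region": True}, False),
        ],
    )
    def test_boundary_semantics(self, override, kept):
        df = pd.DataFrame([pz_record(**override)])
        assert (len(pz.pz_candidate_filter(df)) == 1) is kept

    def test_all_boundaries_simultaneously(self):
        df = pd.DataFrame(
            [pz_record(vaf_exome=0.34, alt_reads_proband=5, alt_reads_father=1,
                       alt_reads_mother=1, depth_father=10, depth_mother=10, tlod=5.0)]
        )
        assert len(pz.pz_candidate_filter(df)) == 1

    def test_missing_field_names_the_field(self):
        df = pd.DataFrame([pz_record()]).drop(columns=["tlod"])
        with pytest.raises(FilterError, match="tlod"):
            pz.pz_candidate_filter(df)

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            [
                pz_record(
                    vaf_exome=rng.uniform(0, 0.6),
                    alt_reads_proband=rng.integers(0, 20),
                    tlod=rng.uniform(0, 30),
                )
                for _ in range(200)
            ]
        )
        strict = set(pz.pz_candidate_filter(df).index)
        relaxed = set(
            pz.pz_candidate_filter(df, max_vaf=0.5, min_alt_proband=3, min_tlod=2).index
        )
        assert strict <= relaxed


class TestTasClassify:
    @pytest.mark.parametrize(
        "alt,depth,label",
        [
            (4800, 10000, "likely_gDNM"),  # 48%
            (4750, 10000, "likely_gDNM"),  # boundary inclusive on the gDNM side
            (4749, 10000, "pzDNM"),
            (100, 10000, "pzDNM"),  # 1% inclusive
            (50, 10000, "fail"),  # 0.5%
        ],
    )
    def test_vaf_windows(self, alt, depth, label):
        assert pz.tas_classify(alt, depth)[0] == label

    def test_exact_half_is_maximally_heterozygous(self):
        _, p = pz.tas_classify(5000, 10000)
        assert p == pytest.approx(1.0)

    def test_deep_mosaic_rejects_germline_hypothesis(self):
        _, p = pz.tas_classify(2000, 10000)  # VAF 20% at depth 10k
        assert p < 1e-100

    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            pz.tas_classify(11, 10)


class TestSubstitutionSpectrum:
    def test_purine_reference_complemented_with_cpg_context(self):
        # G>A whose 5' neighbor is C: the complementary strand carries C>T
        # with a 3' G, i.e. a CpG transition
        df = pd.DataFrame(
            {"ref": ["G"], "alt": ["A"], "context_5p": ["C"], "context_3p": ["T"]}
        )
        spec = pz.substitution_spectrum(df)
        assert spec["C>T(CpG)"] == 1 and spec.sum() == 1

    def test_t_to_g_counts_as_a_to_c(self):
        df = pd.DataFrame(
            {"ref": ["T"], "alt": ["G"], "context_5p": ["A"], "context_3p": ["A"]}
        )
        assert pz.substitution_spectrum(df)["A>C"] == 1

    def test_total_conserved_and_non_snv_skipped(self):
        df = pd.DataFrame(
            {
                "ref": ["C", "A", "AT"],
                "alt": ["T", "G", "A"],
                "context_5p": ["A", "A", "A"],
                "context_3p": ["A", "A", "A"],
            }
        )
        with pytest.warns(UserWarning, match="non-SNV"):
            spec = pz.substitution_spectrum(df)
        assert spec.sum() == 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_reverse_complement_invariance(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        n = 30
        ref = rng.choice(bases, n)
        alt = np.array([rng.choice([b for b in bases if b != r]) for r in ref])
        c5, c3 = rng.choice(bases, n), rng.choice(bases, n)
        df = pd.DataFrame({"ref": ref, "alt": alt, "context_5p": c5, "context_3p": c3})
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = pd.DataFrame(
            {
                "ref": [comp[b] for b in ref],
                "alt": [comp[b] for b in alt],
                "context_5p": [comp[b] for b in c3],
                "context_3p": [comp[b] for b in c5],
            }
        )
        assert pz.substitution_spectrum(df).equals(pz.substitution_spectrum(rc))


class TestSpectrumCompare:
    def test_identical_spectra(self):
        a = pd.Series([3, 2, 1, 1, 1, 2, 2], index=pz.SPECTRUM_CATEGORIES)
        res = pz.spectrum_compare(a, a)
        assert res.fisher_p == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_exact_path_matches_reference_implementation(self):
        # oracle: R fisher.test on the same 2x7 table -> 0.9807097
        a = pd.Series([3, 2, 1, 1, 1, 2, 2], index=pz.SPECTRUM_CATEGORIES)
        b = pd.Series([1, 1, 2, 0, 1, 1, 1], index=pz.SPECTRUM_CATEGORIES)
        res = pz.spectrum_compare(a, b)
        assert res.method == "exact"
        assert res.fisher_p == pytest.approx(0.9807097, abs=1e-6)

    def test_monte_carlo_tracks_exact_reference(self):
        # oracle: R fisher.test (network algorithm) -> 0.0005616797
        a = pd.Series([7, 11, 2, 2, 10, 15, 13], index=pz.SPECTRUM_CATEGORIES)
        b = pd.Series([7, 6, 4, 12, 5, 1, 10], index=pz.SPECTRUM_CATEGORIES)
        res = pz.spectrum_compare(a, b, n_resamples=200_000, seed=1)
        assert res.method == "monte_carlo"
        assert res.fisher_p == pytest.approx(0.0005616797, rel=0.3)

    def test_anticorrelated_spectra(self):
        a = pd.Series([0, 30, 0, 1, 1, 1, 1], index=pz.SPECTRUM_CATEGORIES)
        b = pd.Series([1, 0, 1, 30, 1, 1, 1], index=pz.SPECTRUM_CATEGORIES)
        res = pz.spectrum_compare(a, b, n_resamples=5000, seed=0)
        assert res.pearson_r < 0

    def test_cohort_scale_comparison_runs(self):
        rng = np.random.default_rng(2)
        p = [0.1, 0.22, 0.09, 0.09, 0.1, 0.17, 0.23]
        a = pd.Series(rng.multinomial(364, p), index=pz.SPECTRUM_CATEGORIES)
        b = pd.Series(rng.multinomial(45, p), index=pz.SPECTRUM_CATEGORIES)
        res = pz.spectrum_compare(a, b, n_resamples=100_000, seed=3)
        assert 0 < res.fisher_p <= 1

    def test_zero_total_rejected(self):
        a = pd.Series([1] * 7, index=pz.SPECTRUM_CATEGORIES)
        z = pd.Series([0] * 7, index=pz.SPECTRUM_CATEGORIES)
        with pytest.raises(ValueError):
            pz.spectrum_compare(a, z)
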