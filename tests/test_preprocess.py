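"""Preprocessing chain: tpm, expression/blank filters, outliers, Box-Cox,
predictor scaling."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hybridpred as hp
from hybridpred.containers import OmicsMatrix
from hybridpred.preprocess import (PreprocessReport, normalize_batches,
                                   preprocess_metabolites)


def om(values, layer="transcriptomic", columns=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])],
                      columns=columns)
    return OmicsMatrix(df, layer)


class TestTpm:
    def test_hand_computed_example(self):
        # counts (10, 10), lengths (1 kb, 2 kb): rates (10, 5) -> tpm 2/3, 1/3
        res = hp.tpm_normalize(om([[10, 10]]), pd.Series([1.0, 2.0], index=[0, 1]))
        np.testing.assert_allclose(res.values[0], [1e6 * 2 / 3, 1e6 / 3], rtol=1e-9)

    def test_symmetry_equal_counts_equal_lengths(self):
        res = hp.tpm_normalize(om([[7, 7, 7, 7]]), pd.Series(2.0, index=range(4)))
        np.testing.assert_allclose(res.values[0], 2.5e5)

    def test_single_feature_is_one_million(self):
        for c in (1, 999):
            res = hp.tpm_normalize(om([[c]]), pd.Series([3.0], index=[0]))
            assert res.values[0, 0] == pytest.approx(1e6)

    def test_zero_total_names_individual(self):
        with pytest.raises(ValueError, match="s1"):
            hp.tpm_normalize(om([[5, 5], [0, 0]]), pd.Series(1.0, index=[0, 1]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_sum_to_one_million(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(20.0, size=(4, 30)).astype(float)
        counts[:, 0] += 1  # guard against all-zero rows
        lengths = pd.Series(rng.uniform(0.2, 10.0, 30), index=range(30))
        res = hp.tpm_normalize(om(counts), lengths)
        np.testing.assert_allclose(res.values.sum(axis=1), 1e6, rtol=1e-6)


class TestExpressionFilter:
    def test_threshold_inclusive_and_counts(self):
        mat = om(np.array([[0, 4.9, 5, 7, 100]] * 3), columns=list("abcde"))
        kept = hp.filter_expressed(mat, 5.0)
        assert kept.features == ["c", "d", "e"]

    def test_all_below_threshold_warns_empty(self):
        with pytest.warns(UserWarning):
            kept = hp.filter_expressed(om(np.zeros((3, 4))), 5.0)
        assert kept.shape[1] == 0

    def test_idempotent(self, rng):
        mat = om(rng.exponential(10, size=(6, 40)))
        once = hp.filter_expressed(mat, 5.0)
        twice = hp.filter_expressed(once, 5.0)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestBlankFilter:
    def test_ratio_above_threshold_kept(self):
        s = om([[10.0], [10.0]], "metabolic", ["m1"])
        b = om([[4.0]], "metabolic", ["m1"])
        assert hp.filter_blanks(s, b).features == ["m1"]

    def test_ratio_exactly_two_removed(self):
        s = om([[8.0], [8.0]], "metabolic", ["m1"])
        b = om([[4.0]], "metabolic", ["m1"])
        assert hp.filter_blanks(s, b).features == []

    def test_zero_blank_kept(self):
        s = om([[1.0, 3.0]], "metabolic", ["m1", "m2"])
        b = om([[0.0, 0.0]], "metabolic", ["m1", "m2"])
        assert hp.filter_blanks(s, b).features == ["m1", "m2"]

    def test_disjoint_features_error(self):
        s = om([[1.0]], "metabolic", ["m1"])
        b = om([[1.0]], "metabolic", ["other"])
        with pytest.raises(ValueError, match="disjoint"):
            hp.filter_blanks(s, b)


class TestOutliers:
    def test_constant_vector_untouched(self):
        x = np.full(10, 3.3)
        np.testing.assert_array_equal(hp.remove_outliers(x), x)

    def test_spike_vector_numeric_rule(self):
        x = np.array([0.0, 0, 0, 0, 100])
        med, sd = np.median(x), np.std(x, ddof=1)
        out = hp.remove_outliers(x)
        if abs(100 - med) > 4 * sd:
            assert np.isnan(out[-1])
        else:
            assert out[-1] == 100.0

    def test_normal_sample_rarely_clipped(self, rng):
        x = rng.normal(size=10_000)
        removed = np.isnan(hp.remove_outliers(x)).sum()
        assert removed <= 3  # two-sided P(|z|>4) ~ 6e-5

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            hp.remove_outliers(np.array([1.0, 2.0]))


class TestBoxCox:
    def test_lambda_one_is_shifted_identity(self):
        x = np.array([1.0, 2.0, 5.0])
        y, lam = hp.boxcox_transform(x, lam=1.0)
        np.testing.assert_allclose(y, x - 1)

    def test_lambda_zero_is_log(self):
        x = np.array([1.0, np.e, np.e**2])
        y, _ = hp.boxcox_transform(x, lam=0.0)
        np.testing.assert_allclose(y, [0, 1, 2], atol=1e-12)

    def test_lognormal_lambda_near_zero(self, rng):
        x = rng.lognormal(0.0, 1.0, size=2000)
        _, lam = hp.boxcox_transform(x)
        assert abs(lam) < 0.2

    def test_skewness_reduced_on_lognormal(self, rng):
        from scipy.stats import skew
        x = rng.lognormal(1.0, 0.8, size=1500)
        y, _ = hp.boxcox_transform(x)
        assert abs(skew(y)) <= abs(skew(x))


class TestScaling:
    def test_full_range_genomic_column_fixed_point(self):
        mat = om([[0.0], [1.0], [2.0]], "genomic")
        np.testing.assert_allclose(hp.scale_predictors(mat).values.ravel(), [0, 1, 2])

    def test_transcript_minmax(self):
        mat = om([[10.0], [20.0], [30.0]])
        np.testing.assert_allclose(hp.scale_predictors(mat).values.ravel(), [0, 0.5, 1])

    def test_constant_column_midpoint_flagged(self):
        rep = PreprocessReport()
        mat = om([[5.0, 1.0], [5.0, 2.0]], "genomic", ["c", "v"])
        out = hp.scale_predictors(mat, rep)
        np.testing.assert_allclose(out.data["c"], 1.0)
        assert rep.constant_columns["genomic"] == ["c"]


class TestChain:
    def test_batch_normalization_aligns_day_medians(self, rng):
        X = rng.lognormal(2, 0.3, size=(12, 5))
        X[6:] *= 3.0  # day-2 detector response
        mat = om(X, "metabolic")
        batch = pd.Series(["d1"] * 6 + ["d2"] * 6, index=mat.data.index)
        out = normalize_batches(mat, batch=batch)
        med1 = out.data.iloc[:6].median()
        med2 = out.data.iloc[6:].median()
        np.testing.assert_allclose(med1, med2, rtol=1e-9)

    def test_full_metabolite_chain_runs_and_reports(self, rng):
        X = rng.lognormal(2, 0.5, size=(20, 8))
        mat = om(X, "metabolic", [f"m{i}" for i in range(8)])
        blanks = om(np.full((3, 8), 1e-3), "metabolic", [f"m{i}" for i in range(8)])
        rep = PreprocessReport()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = preprocess_metabolites(mat, blanks, report=rep)
        assert out.shape == (20, 8)
        assert len(rep.boxcox_lambda) == 8
        assert rep.steps[-1]["features_out"] <= rep.steps[-1]["features_in"]
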