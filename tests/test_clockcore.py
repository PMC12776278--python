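"""Preprocessing, clock application, and methylation summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipoclock import clockcore
from adipoclock.types import ClockModel, OmicsMatrix

from conftest import beta_matrix, counts_matrix


class TestFilterExpression:
    def test_gene_at_exact_boundary_kept(self):
        # 10 reads in exactly 20% of 10 samples
        row = [10, 10] + [0] * 8
        m = counts_matrix([row, [100] * 10])
        kept = clockcore.filter_expression(m)
        assert list(kept.data.index) == ["g0", "g1"]

    def test_gene_below_read_threshold_removed(self):
        m = counts_matrix([[9] * 10, [10] * 10])
        kept = clockcore.filter_expression(m)
        assert list(kept.data.index) == ["g1"]

    def test_all_zero_matrix_retains_nothing(self):
        kept = clockcore.filter_expression(counts_matrix(np.zeros((5, 4))))
        assert kept.data.shape == (0, 4)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            clockcore.filter_expression(counts_matrix(np.empty((0, 0))))


class TestFilterMethylation:
    def test_quarter_bad_removed(self):
        beta = beta_matrix(np.full((1, 4), 0.5))
        detp = pd.DataFrame([[0.02, 0.001, 0.001, 0.001]], index=beta.data.index, columns=beta.data.columns)
        kept = clockcore.filter_methylation(beta, detp)
        assert kept.data.shape[0] == 0

    def test_clean_matrix_identity(self):
        beta = beta_matrix(np.full((3, 4), 0.5))
        detp = pd.DataFrame(np.zeros((3, 4)), index=beta.data.index, columns=beta.data.columns)
        kept = clockcore.filter_methylation(beta, detp)
        assert kept.data.shape == (3, 4)

    def test_twenty_percent_bad_kept(self):
        beta = beta_matrix(np.full((1, 10), 0.5))
        p = np.full((1, 10), 1e-3)
        p[0, :2] = 0.5
        detp = pd.DataFrame(p, index=beta.data.index, columns=beta.data.columns)
        kept = clockcore.filter_methylation(beta, detp)
        assert kept.data.shape[0] == 1

    def test_shape_mismatch_rejected(self):
        beta = beta_matrix(np.full((2, 4), 0.5))
        detp = pd.DataFrame(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="shape"):
            clockcore.filter_methylation(beta, detp)


class TestMethylationSummaries:
    def test_constant_beta_mean(self):
        assert clockcore.mean_methylation(beta_matrix(np.full((4, 3), 0.3))).eq(0.3).all()

    def test_balanced_extremes_mean_half(self):
        m = beta_matrix(np.vstack([np.zeros((2, 3)), np.ones((2, 3))]))
        assert clockcore.mean_methylation(m).eq(0.5).all()

    def test_mean_matches_brute_force(self, rng):
        values = rng.uniform(0, 1, size=(7, 5))
        result = clockcore.mean_methylation(beta_matrix(values))
        for j in range(5):
            assert result.iloc[j] == pytest.approx(sum(values[:, j]) / 7)

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="no CpGs"):
            clockcore.mean_methylation(beta_matrix(np.empty((0, 3))))

    def test_entropy_maximal_at_half(self):
        assert clockcore.shannon_entropy(beta_matrix(np.full((5, 2), 0.5))).eq(1.0).all()

    def test_entropy_near_zero_at_extremes(self):
        e = clockcore.shannon_entropy(beta_matrix(np.zeros((5, 2))))
        assert (e < 2.2e-5).all()

    def test_entropy_matches_brute_force(self, rng):
        values = rng.uniform(0.01, 0.99, size=(6, 4))
        result = clockcore.shannon_entropy(beta_matrix(values))
        for j in range(4):
            acc = 0.0
            for i in range(6):
                b = min(max(values[i, j], 1e-6), 1 - 1e-6)
                acc += -(b * np.log2(b) + (1 - b) * np.log2(1 - b))
            assert result.iloc[j] == pytest.approx(acc / 6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_entropy_bounded(self, seed):
        values = np.random.default_rng(seed).uniform(0, 1, size=(5, 4))
        e = clockcore.shannon_entropy(beta_matrix(values))
        assert ((e >= 0) & (e <= 1)).all()


class TestRLE:
    def test_identical_samples_equal_factors(self):
        m = counts_matrix(np.tile([[10.0], [20.0], [5.0]], (1, 3)))
        f = clockcore.rle_size_factors(m)
        assert np.allclose(f, f.iloc[0])
        norm = clockcore.rle_normalize(m)
        assert np.allclose(norm.iloc[:, 0], norm.iloc[:, 1])

    def test_doubled_sample_factor_ratio_two(self):
        a = np.array([10.0, 30.0, 7.0, 120.0])
        m = counts_matrix(np.column_stack([a, 2 * a]))
        f = clockcore.rle_size_factors(m)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)

    def test_single_sample_factor_one(self):
        m = counts_matrix([[10.0], [20.0]])
        assert clockcore.rle_size_factors(m).iloc[0] == pytest.approx(1.0)

    def test_no_common_positive_gene_rejected(self):
        m = counts_matrix([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="prefilter"):
            clockcore.rle_size_factors(m)

    @given(st.floats(0.5, 20.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_scaling_invariance_up_to_common_scalar(self, factor, seed):
        # scaling one sample rescales the geometric-mean reference by
        # factor^(1/n); relative expression (all between-sample ratios) is
        # exactly preserved
        values = np.random.default_rng(seed).integers(1, 1000, size=(10, 4)).astype(float)
        m = counts_matrix(values)
        scaled = values.copy()
        scaled[:, 2] *= factor
        norm_a = clockcore.rle_normalize(m).to_numpy()
        norm_b = clockcore.rle_normalize(counts_matrix(scaled)).to_numpy()
        ratio = norm_b / norm_a
        assert np.allclose(ratio, ratio[0, 0], rtol=1e-9)
        assert ratio[0, 0] == pytest.approx(factor ** (1 / 4), rel=1e-9)


class TestPreprocessForClock:
    @pytest.fixture
    def tiny_clock(self):
        return ClockModel(
            name="t",
            target="chronological_age",
            features=["g0", "g1", "gX"],
            coefficients=[1.0, -2.0, 0.5],
            intercept=3.0,
            imputation_means=[0.0, 0.0, 0.7],
        )

    @pytest.fixture
    def tiny_sheet(self):
        return pd.DataFrame(
            {
                "sample_id": ["s0", "s1", "s2", "s3"],
                "donor_id": ["d0", "d0", "d1", "d1"],
                "group": ["YY", "YY", "OY", "OY"],
                "role": ["before", "after", "before", "after"],
                "age_months": [4.0, 6.3, 18.0, 20.3],
                "batch": ["b1"] * 4,
            }
        )

    def test_missing_clock_feature_imputed_constant(self, tiny_clock, tiny_sheet, rng):
        counts = counts_matrix(rng.integers(50, 500, size=(3, 4)).astype(float))
        processed = clockcore.preprocess_for_clock(
            counts, tiny_clock, tiny_sheet, reference_groups=("YY",)
        )
        # gX is absent from counts: its centered row is mean - ref median = 0
        assert np.allclose(processed.data.loc["gX"], 0.0)

    def test_reference_median_zero_after_centering(self, tiny_clock, tiny_sheet, rng):
        counts = counts_matrix(rng.integers(50, 500, size=(3, 4)).astype(float))
        processed = clockcore.preprocess_for_clock(
            counts, tiny_clock, tiny_sheet, reference_groups=("YY", "OY")
        )
        ref = ["s0", "s2"]  # 'before' of both groups
        assert np.abs(processed.data[ref].median(axis=1)).max() < 1e-9

    def test_matches_stepwise_hand_computation(self, tiny_clock, tiny_sheet):
        values = np.array(
            [[100.0, 200.0, 50.0, 400.0], [10.0, 10.0, 10.0, 10.0], [30.0, 60.0, 90.0, 120.0]]
        )
        counts = counts_matrix(values)
        processed = clockcore.preprocess_for_clock(
            counts, tiny_clock, tiny_sheet, reference_groups=("YY",), reference_role="before"
        )
        # independent stepwise oracle
        logv = np.log(values)
        ref_genes = np.arange(3)  # all positive everywhere
        geomean = np.exp(logv[ref_genes].mean(axis=1))
        factors = np.median(values[ref_genes] / geomean[:, None], axis=0)
        norm = values / factors
        logged = np.log2(norm + 1)
        mean = logged.mean(axis=1, keepdims=True)
        sd = logged.std(axis=1, keepdims=True)
        z = np.where(sd > 0, (logged - mean) / np.where(sd == 0, 1, sd), 0.0)
        expected = np.vstack([z, np.full((1, 4), 0.7)])
        ref_median = np.median(expected[:, [0]], axis=1, keepdims=True)  # s0 only
        expected = expected - ref_median
        got = processed.data.loc[["g0", "g1", "g2", "gX"]].to_numpy()
        assert np.allclose(got, expected, atol=1e-12)

    def test_provenance_lists_five_steps(self, tiny_clock, tiny_sheet, rng):
        counts = counts_matrix(rng.integers(50, 500, size=(3, 4)).astype(float))
        processed = clockcore.preprocess_for_clock(counts, tiny_clock, tiny_sheet, reference_groups=("YY",))
        assert processed.steps == list(clockcore.PREPROCESS_STEPS)

    def test_absent_reference_group_rejected(self, tiny_clock, tiny_sheet, rng):
        counts = counts_matrix(rng.integers(50, 500, size=(3, 4)).astype(float))
        with pytest.raises(ValueError, match="reference"):
            clockcore.preprocess_for_clock(counts, tiny_clock, tiny_sheet, reference_groups=("OO",))


class TestPredictAge:
    def test_linearity_identity(self, rng):
        clock = ClockModel(
            name="lin",
            target="chronological_age",
            features=[f"g{i}" for i in range(6)],
            coefficients=rng.normal(size=6),
            intercept=2.0,
            imputation_means=np.zeros(6),
        )
        x = pd.DataFrame(rng.normal(size=(6, 4)), index=clock.features)
        delta = pd.DataFrame(rng.normal(size=(6, 4)), index=clock.features)
        p0 = clockcore.predict_age(clock, x)["prediction"].to_numpy()
        p1 = clockcore.predict_age(clock, x + delta)["prediction"].to_numpy()
        expected = clock.coefficients @ delta.to_numpy()
        assert np.allclose(p1 - p0, expected, atol=1e-12)

    def test_missing_feature_rejected(self, rng):
        clock = ClockModel(
            name="m",
            target="log_hazard",
            features=["a", "b"],
            coefficients=[1.0, 1.0],
            intercept=0.0,
            imputation_means=[0.0, 0.0],
        )
        x = pd.DataFrame(rng.normal(size=(1, 3)), index=["a"])
        with pytest.raises(KeyError, match="missing"):
            clockcore.predict_age(clock, x)


class TestStandardizeWithinGroup:
    def _sheet(self, samples, groups):
        return pd.DataFrame(
            {
                "sample_id": samples,
                "donor_id": samples,
                "group": groups,
                "role": ["before"] * len(samples),
                "age_months": 4.0,
                "batch": "b1",
            }
        )

    def test_group_mean_zero_sd_one(self, rng):
        samples = [f"s{i}" for i in range(12)]
        groups = ["YY"] * 6 + ["OY"] * 6
        preds = pd.DataFrame({"sample_id": samples, "prediction": rng.normal(size=12)})
        out = clockcore.standardize_within_group(preds, self._sheet(samples, groups))
        for g in ("YY", "OY"):
            z = out.loc[out["group"] == g, "z"]
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_two_point_group_hand_values(self):
        preds = pd.DataFrame({"sample_id": ["a", "b"], "prediction": [1.0, 3.0]})
        out = clockcore.standardize_within_group(preds, self._sheet(["a", "b"], ["YY", "YY"]))
        assert np.allclose(sorted(out["z"]), [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_group_rejected_by_default(self):
        preds = pd.DataFrame({"sample_id": ["a", "b"], "prediction": [2.0, 2.0]})
        sheet = self._sheet(["a", "b"], ["YY", "YY"])
        with pytest.raises(ValueError, match="constant"):
            clockcore.standardize_within_group(preds, sheet)
        out = clockcore.standardize_within_group(preds, sheet, allow_constant=True)
        assert (out["z"] == 0).all()

    def test_singleton_group_rejected(self):
        preds = pd.DataFrame({"sample_id": ["a", "b", "c"], "prediction": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            clockcore.standardize_within_group(preds, self._sheet(["a", "b", "c"], ["YY", "YY", "OY"]))
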