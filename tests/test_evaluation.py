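"""Prediction, category filtering, zero-intercept regression, error bars,
training-set enumeration and the leave-K-out harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from langcal import (
    CategoryThresholds,
    ClampBounds,
    ConcentrationEstimates,
    LangmuirParams,
    choose_training_sets,
    concentration_category,
    error_bar_lengths,
    leave_k_out,
    predict_concentrations,
    zero_intercept_regression,
)
from langcal.exceptions import (
    InvalidInputError,
    InvalidParamsError,
    NoValidTrainingSetError,
)
from tests.conftest import make_dataset

TRUE = LangmuirParams(a=1000.0, b=10.0, d=100.0)
LADDER = [0.5, 2.0, 8.0, 32.0, 128.0, 512.0]


class TestPredict:
    def test_noiseless_roundtrip(self):
        ds = make_dataset({"p0": TRUE, "p1": TRUE}, LADDER)
        est = predict_concentrations(ds, TRUE, ClampBounds(2000.0, 0.01))
        unclamped = est.table[est.table.clamp == "none"]
        np.testing.assert_allclose(
            unclamped.predicted_concentration,
            unclamped.nominal_concentration,
            rtol=1e-9,
        )

    def test_saturated_rows_flagged(self):
        ds = make_dataset({"p0": TRUE}, LADDER)
        ds.table.loc[0, "mean_intensity"] = TRUE.a + TRUE.d + 50.0
        bounds = ClampBounds(2000.0, 0.01)
        est = predict_concentrations(ds, TRUE, bounds)
        row = est.table.iloc[0]
        assert row.clamp == "saturated_X"
        assert row.predicted_concentration == bounds.X

    def test_excluding_all_probes_gives_empty_estimates(self):
        ds = make_dataset({"p0": TRUE}, LADDER)
        est = predict_concentrations(
            ds, TRUE, ClampBounds(2000.0, 0.01), exclude_probes={"p0"}
        )
        assert len(est) == 0

    def test_non_langmuir_params_rejected(self):
        ds = make_dataset({"p0": TRUE}, LADDER)
        with pytest.raises(InvalidParamsError):
            predict_concentrations(
                ds, LangmuirParams(-5.0, 10.0, 100.0), ClampBounds(2000.0, 0.01)
            )


@pytest.mark.parametrize(
    "c, expected",
    [(0.25, "low"), (0.5, "low"), (1.0, "medium"), (64.0, "medium"),
     (256.0, "high"), (512.0, "high")],
)
def test_concentration_category(c, expected):
    thr = CategoryThresholds(low_max=0.5, high_min=256.0)
    assert concentration_category(c, thr) == expected


def test_category_thresholds_ordering():
    with pytest.raises(InvalidInputError):
        CategoryThresholds(low_max=10.0, high_min=5.0)


class TestZeroInterceptRegression:
    def test_exact_proportionality(self):
        res = zero_intercept_regression([1, 2, 3], [2, 4, 6], scale="linear")
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope_p_value == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        # m = (1*3 + 2*3) / (1 + 4) = 9/5; R^2 = 1 - SSE/sum(y^2) = 1 - 1.8/18
        res = zero_intercept_regression([1, 2], [3, 3], scale="linear")
        assert res.slope == pytest.approx(1.8)
        assert res.r_squared == pytest.approx(0.9)

    def test_identity_vector(self):
        y = [0.3, 5.0, 12.0]
        res = zero_intercept_regression(y, y, scale="linear")
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_intercept_free_ols(self):
        """Agreement with an independent regression routine fitted
        without a constant term, on random inputs."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(3, 40)
            x = rng.uniform(0.1, 100, size=n)
            y = 2.0 * x * rng.lognormal(0, 0.3, size=n)
            mine = zero_intercept_regression(x, y, scale="linear")
            ols = sm.OLS(y, x).fit()
            assert mine.slope == pytest.approx(ols.params[0], rel=1e-12)
            assert mine.r_squared == pytest.approx(ols.rsquared, rel=1e-12)
            assert mine.slope_p_value == pytest.approx(ols.pvalues[0], abs=1e-12)

    def test_log2_scale(self):
        x = np.array([2.0, 4.0, 8.0])
        res = zero_intercept_regression(x, x * 2, scale="log2")
        # log2(y) = log2(x) + 1 is NOT proportional to log2(x): slope > 1
        assert res.scale == "log2"
        assert res.slope > 1.0

    @pytest.mark.parametrize(
        "x, y, scale",
        [
            ([1, 2], [1], "linear"),  # length mismatch
            ([1], [1], "linear"),  # n < 2
            ([1, -2], [1, 2], "log2"),  # nonpositive under log2
            ([0, 0], [1, 2], "linear"),  # all-zero x
        ],
    )
    def test_invalid_inputs(self, x, y, scale):
        with pytest.raises(InvalidInputError):
            zero_intercept_regression(x, y, scale=scale)

    @settings(max_examples=100, derandomize=True)
    @given(
        k=st.floats(0.1, 50.0),
        seed=st.integers(0, 10_000),
    )
    def test_scaling_y_scales_slope_not_r2(self, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.5, 20, size=8)
        y = x * rng.lognormal(0, 0.2, size=8)
        base = zero_intercept_regression(x, y, scale="linear")
        scaled = zero_intercept_regression(x, k * y, scale="linear")
        assert scaled.slope == pytest.approx(k * base.slope, rel=1e-9)
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-9)


class TestErrorBars:
    @staticmethod
    def _estimates(pairs):
        return ConcentrationEstimates(
            pd.DataFrame(
                [
                    {
                        "probe_id": f"p{i}",
                        "condition_id": "c",
                        "nominal_concentration": c,
                        "predicted_concentration": v,
                        "clamp": "none",
                    }
                    for i, (c, v) in enumerate(pairs)
                ]
            )
        )

    def test_sample_sd(self):
        out = error_bar_lengths(self._estimates([(8.0, 8.0), (8.0, 12.0)]))
        assert out[8.0] == pytest.approx(np.sqrt(8.0))  # ddof=1 -> 2.828...

    def test_identical_predictions(self):
        out = error_bar_lengths(self._estimates([(4.0, 5.0)] * 3))
        assert out[4.0] == 0.0

    def test_single_prediction_maps_to_zero(self):
        out = error_bar_lengths(self._estimates([(2.0, 3.0)]))
        assert out[2.0] == 0.0

    def test_empty(self):
        assert error_bar_lengths(self._estimates([])) == {}


class TestChooseTrainingSets:
    def test_exhaustive_branch(self):
        sets = choose_training_sets(["a", "b", "c"], K=1, max_draws=42, seed=0)
        assert sets == [frozenset("a"), frozenset("b"), frozenset("c")]

    def test_sampled_branch_is_distinct_and_sized(self):
        probes = [f"p{i}" for i in range(42)]
        sets = choose_training_sets(probes, K=2, max_draws=42, seed=9)
        assert len(sets) == 42
        assert len(set(sets)) == 42
        assert all(len(s) == 2 for s in sets)

    def test_deterministic_under_seed(self):
        probes = [f"p{i}" for i in range(20)]
        a = choose_training_sets(probes, 3, 15, seed=4)
        b = choose_training_sets(probes, 3, 15, seed=4)
        assert a == b

    @pytest.mark.parametrize("K", [0, 3])
    def test_k_out_of_range(self, K):
        with pytest.raises(InvalidInputError):
            choose_training_sets(["a", "b", "c"], K=K, max_draws=5, seed=0)


class TestLeaveKOut:
    def test_noiseless_perfect_scores(self, noiseless_dataset):
        cv = leave_k_out(noiseless_dataset, K=1, max_draws=100, seed=0)
        assert len(cv.results) == noiseless_dataset.n_probes
        np.testing.assert_allclose(cv.slopes, 1.0, atol=1e-9)
        np.testing.assert_allclose(cv.r_squared, 1.0, atol=1e-9)
        assert cv.n_skipped == 0

    def test_zero_holdout_rejected(self, noiseless_dataset):
        with pytest.raises(InvalidInputError):
            leave_k_out(noiseless_dataset, K=0)

    def test_loo_heldout_union_covers_probe_universe(self, noiseless_dataset):
        cv = leave_k_out(noiseless_dataset, K=1, max_draws=100, seed=0)
        universe = set(noiseless_dataset.probe_ids)
        held_out = set()
        for res in cv.results:
            held_out |= universe - res.training_probes
        assert held_out == universe

    def test_low_category_rows_dropped(self, noiseless_dataset):
        thr = CategoryThresholds(low_max=0.5, high_min=256.0)
        cv = leave_k_out(
            noiseless_dataset, K=1, max_draws=100, seed=0, thresholds=thr
        )
        for res in cv.results:
            assert all(c > 0.5 for c in res.per_concentration_sd)
        with_low = leave_k_out(
            noiseless_dataset, K=1, max_draws=100, seed=0, thresholds=thr,
            include_low=True,
        )
        assert with_low.results[0].n_points > cv.results[0].n_points

    def test_all_training_sets_rejected_raises(self):
        flat = {
            f"p{i}": None for i in range(3)
        }
        rows = [
            {
                "probe_id": p,
                "condition_id": f"c{j}",
                "mean_intensity": 100.0,  # constant response everywhere
                "nominal_concentration": c,
                "n_replicates": 1,
            }
            for p in flat
            for j, c in enumerate(LADDER)
        ]
        from langcal import SpikeInDataset

        ds = SpikeInDataset(pd.DataFrame(rows))
        with pytest.raises(NoValidTrainingSetError):
            leave_k_out(ds, K=2, max_draws=10, seed=0)

    def test_heterogeneity_to_zero_approaches_perfect_r2(self):
        """As per-probe parameter spread shrinks, leave-one-out R^2 -> 1."""
        from langcal import SimulationConfig, average_replicates, simulate

        medians = []
        for cv_level in (0.3, 0.05, 0.0):
            cfg = SimulationConfig(
                n_probes=10, probe_cv=cv_level, noise_sd_log=0.0, seed=21
            )
            raw, design, _ = simulate(cfg)
            ds = average_replicates(raw, design)
            out = leave_k_out(ds, K=1, max_draws=100, seed=0)
            medians.append(float(np.median(out.r_squared)))
        assert medians[-1] == pytest.approx(1.0, abs=1e-9)
        assert medians[0] <= medians[1] + 1e-12 <= medians[2] + 2e-12
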