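"""Ratio and maximum-likelihood estimators of (P, r) from category counts."""

import math

import numpy as np
import pytest

from cesdexp import (
    CategoryCounts,
    ModelParams,
    aggregate_params,
    estimate_mle,
    estimate_ratio,
    log_likelihood,
    loglinear_slope,
    parallelism_check,
    sample_item,
)


class TestRatioEstimator:
    @pytest.mark.parametrize(
        "counts, P_exp, r_exp",
        [
            ((650, 200, 100, 50), 0.2, 0.5),
            ((850, 100, 30, 6), 100 / 986, (0.3 + 0.2) / 2),
            ((900, 100, 0, 0), 0.1, 0.0),  # empty upper tail -> r = 0
        ],
    )
    def test_defined_cases(self, counts, P_exp, r_exp):
        est = estimate_ratio(CategoryCounts(*counts))
        assert est.defined
        assert est.P_hat == pytest.approx(P_exp, abs=1e-12)
        assert est.r_hat == pytest.approx(r_exp, abs=1e-12)
        assert est.n_total == sum(counts)

    @pytest.mark.parametrize(
        "counts",
        [
            (1000, 0, 0, 0),  # no "some": P unidentified
            (900, 0, 50, 50),  # n_some = 0
            (800, 150, 0, 50),  # mass beyond an empty middle category
        ],
    )
    def test_undefined_cases(self, counts):
        est = estimate_ratio(CategoryCounts(*counts))
        assert not est.defined
        assert math.isnan(est.P_hat) and math.isnan(est.r_hat)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError, match="empty counts"):
            CategoryCounts(0, 0, 0, 0)


def _grid_mle(counts: CategoryCounts, step=1e-3):
    """Independent dense grid-search oracle for the MLE."""
    best, best_ll = None, -np.inf
    for r in np.arange(step, 1.5, step):
        s = r * r + r + 1.0
        for P in np.arange(step, 1.0 / s, step):
            ll = log_likelihood(counts, ModelParams(P, r))
            if ll > best_ll:
                best, best_ll = (P, r), ll
    return best, best_ll


class TestMLE:
    def test_exact_model_counts_recovered(self, exact_counts):
        """Empirical distribution inside the model family: MLE = ratio estimate."""
        est = estimate_mle(exact_counts)
        assert est.defined
        assert est.P_hat == pytest.approx(0.2, abs=1e-9)
        assert est.r_hat == pytest.approx(0.5, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        counts = CategoryCounts(850, 100, 30, 6)
        est = estimate_mle(counts)
        (P_grid, r_grid), ll_grid = _grid_mle(counts)
        assert est.P_hat == pytest.approx(P_grid, abs=2e-3)
        assert est.r_hat == pytest.approx(r_grid, abs=2e-3)
        assert log_likelihood(counts, est.params) >= ll_grid - 1e-9

    def test_dominates_ratio_estimate(self):
        """MLE log-likelihood >= ratio-estimate log-likelihood, always."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            r = rng.uniform(0.1, 1.0)
            P = rng.uniform(0.05, 1.0 / (r * r + r + 1.0))
            counts = sample_item(ModelParams(P, r), 500, rng)
            ratio = estimate_ratio(counts)
            if not ratio.defined or ratio.r_hat <= 0:
                continue
            mle = estimate_mle(counts)
            assert log_likelihood(counts, mle.params) >= (
                log_likelihood(counts, ratio.params) - 1e-9
            )

    def test_all_rarely_undefined(self):
        est = estimate_mle(CategoryCounts(1000, 0, 0, 0))
        assert not est.defined


@pytest.mark.parametrize("P", [0.1, 0.2, 0.3])
@pytest.mark.parametrize("r", [0.25, 0.5, 0.75])
def test_parameter_recovery(P, r):
    """Both estimators recover (P, r) from n=10,000 simulated responses."""
    seed = 1000 + int(P * 100) * 10 + int(r * 100)
    counts = sample_item(ModelParams(P, r), 10_000, seed)
    for est in (estimate_ratio(counts), estimate_mle(counts)):
        assert est.defined
        assert abs(est.P_hat - P) < 0.02
        assert abs(est.r_hat - r) < 0.05


class TestAggregation:
    def test_mean_of_defined(self):
        from cesdexp.estimation import ParamEstimate

        ests = [
            estimate_ratio(CategoryCounts(650, 200, 100, 50)),  # (0.2, 0.5)
            ParamEstimate(0.3, 0.3, "ratio", 1000, True),
        ]
        mean_P, mean_r, skipped = aggregate_params(ests)
        assert (mean_P, mean_r, skipped) == pytest.approx((0.25, 0.4, 0))
        single = aggregate_params(ests[:1])
        assert single == pytest.approx((0.2, 0.5, 0))

    def test_undefined_skipped_and_counted(self):
        from cesdexp.estimation import ParamEstimate

        ests = [
            ParamEstimate(0.2, 0.5, "ratio", 1000, True),
            ParamEstimate(math.nan, math.nan, "ratio", 1000, False),
        ]
        assert aggregate_params(ests) == pytest.approx((0.2, 0.5, 1))

    def test_all_undefined_raises(self):
        from cesdexp.estimation import ParamEstimate

        with pytest.raises(ValueError, match="all estimates undefined"):
            aggregate_params([ParamEstimate(math.nan, math.nan, "ratio", 10, False)])


class TestLoglinearSlope:
    def test_exact_geometric_counts(self, exact_counts):
        assert loglinear_slope(exact_counts) == pytest.approx(
            math.log(0.5), abs=1e-12
        )

    def test_flat_counts(self):
        assert loglinear_slope(CategoryCounts(0, 100, 100, 100)) == 0.0

    def test_three_point_ols(self):
        # OLS slope over equally spaced x reduces to (y3 - y1) / 2
        y = [math.log(400), math.log(150), math.log(60)]
        x = [0.0, 1.0, 2.0]
        xbar, ybar = sum(x) / 3, sum(y) / 3
        ols = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y)) / sum(
            (xi - xbar) ** 2 for xi in x
        )
        assert loglinear_slope(CategoryCounts(0, 400, 150, 60)) == pytest.approx(
            ols, abs=1e-12
        )

    def test_zero_upper_count_undefined(self):
        assert math.isnan(loglinear_slope(CategoryCounts(900, 100, 0, 0)))


class TestParallelism:
    def test_identical_geometric_items(self):
        items = [CategoryCounts(650, 200, 100, 50), CategoryCounts(475, 300, 150, 75)]
        res = parallelism_check(items)
        assert res.spread == pytest.approx(0.0, abs=1e-12)
        assert res.parallel

    def test_distinct_ratios_spread(self):
        items = [
            CategoryCounts(650, 200, 100, 50),  # r = 0.5
            CategoryCounts(0, 640, 160, 40),  # r = 0.25
        ]
        res = parallelism_check(items)
        assert res.spread == pytest.approx(math.log(2), abs=1e-12)
        assert not res.parallel

    def test_simulated_common_r_spread_shrinks(self):
        """On-model items with a common r: slope spread small at n = 5,000."""
        rng = np.random.default_rng(42)
        items = [
            sample_item(ModelParams(P, 0.5), 5_000, rng)
            for P in (0.1, 0.15, 0.2, 0.25)
        ]
        res = parallelism_check(items)
        assert res.parallel and res.spread < 0.15

    def test_too_few_defined_slopes(self):
        with pytest.raises(ValueError, match="at least 2"):
            parallelism_check([CategoryCounts(650, 200, 100, 50)])
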