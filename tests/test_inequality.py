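"""Inequality measures: ridit scores, RII/SII fits, Erreygers' index, VIF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqcov import (
    SurveyDesign,
    erreygers_ci,
    estimate_rii,
    estimate_sii,
    generate_survey,
    ridit_scores,
    simple_measures,
    vif,
    weighted_fractional_rank,
)
from eqcov.synthetic_data import SimulationConfig, SimulationTruth, StageTruth


def frame(n, ranks=None, weight=1.0):
    return pd.DataFrame(
        {"stratum_id": 1, "psu_id": np.arange(n), "weight": weight,
         **({"rank": ranks} if ranks is not None else {})}
    )


def glm_poisson_log_oracle(y, X, tol=1e-12, max_iter=200):
    """Independently coded IRLS for an unweighted log-link Poisson fit.

    Newton-Raphson on the Poisson log-likelihood with log link:
    beta <- beta + (X' W X)^-1 X'(y - mu), W = diag(mu).
    """
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-6))
    for _ in range(max_iter):
        mu = np.exp(X @ beta)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestRiditScores:
    def test_equal_quintiles(self):
        labels = pd.Series(["Q1", "Q2", "Q3", "Q4", "Q5"] * 4)
        rs = ridit_scores(labels, np.ones(20),
                          order=["Q1", "Q2", "Q3", "Q4", "Q5"])
        assert rs.scores == pytest.approx((0.1, 0.3, 0.5, 0.7, 0.9))

    def test_unequal_group_shares(self):
        # proportions (0.4, 0.3, 0.2, 0.05, 0.05) -> cumulative midpoints
        labels = pd.Series(
            ["a"] * 8 + ["b"] * 6 + ["c"] * 4 + ["d"] * 1 + ["e"] * 1
        )
        rs = ridit_scores(labels, np.ones(20), order=list("abcde"))
        assert rs.scores == pytest.approx((0.20, 0.55, 0.80, 0.925, 0.975))

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            ridit_scores(pd.Series(["a", "a"]), np.ones(2), order=["a"])

    def test_empty_group_dropped(self):
        labels = pd.Series(["a", "c", "a", "c"])
        rs = ridit_scores(labels, np.ones(4), order=["a", "b", "c"])
        assert rs.categories == ("a", "c")

    @given(
        st.lists(st.sampled_from("abcd"), min_size=4, max_size=60).filter(
            lambda v: len(set(v)) >= 2
        ),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_weighted_mean_is_half(self, labels, seed):
        """Midpoint identity: the weighted mean ridit is exactly 0.5."""
        rng = np.random.default_rng(seed)
        w = rng.gamma(5.0, 1.0, len(labels)) + 0.01
        labels = pd.Series(labels)
        rs = ridit_scores(labels, w, order=sorted(set(labels)))
        per_record = rs.to_records(labels)
        assert np.average(per_record, weights=w) == pytest.approx(0.5)


class TestFractionalRank:
    def test_equal_quintiles_broadcast(self):
        labels = pd.Series(["Q1", "Q2", "Q3", "Q4", "Q5"] * 2)
        r = weighted_fractional_rank(labels, np.ones(10))
        assert sorted(set(np.round(r, 10))) == [0.1, 0.3, 0.5, 0.7, 0.9]

    def test_single_group_is_half(self):
        r = weighted_fractional_rank(pd.Series(["a"] * 5), np.ones(5))
        assert (r == 0.5).all()

    def test_two_equal_groups(self):
        r = weighted_fractional_rank(pd.Series(["a", "b"]), np.ones(2))
        assert list(r) == [0.25, 0.75]


class TestSimpleMeasures:
    def test_difference_and_ratio(self):
        diff, ratio = simple_measures({"Q5": 0.9, "Q1": 0.3}, "Q5", "Q1")
        assert diff.point == pytest.approx(0.6)
        assert ratio.point == pytest.approx(3.0)

    def test_equal_coverage_identity(self):
        diff, ratio = simple_measures({"hi": 0.4, "lo": 0.4}, "hi", "lo")
        assert diff.point == 0.0 and ratio.point == 1.0

    def test_zero_disadvantaged_flags_ratio(self):
        diff, ratio = simple_measures({"hi": 0.4, "lo": 0.0}, "hi", "lo")
        assert ratio.undefined and np.isnan(ratio.point)
        assert diff.point == pytest.approx(0.4)

    def test_missing_group_rejected(self):
        with pytest.raises(KeyError):
            simple_measures({"hi": 0.4}, "hi", "lo")


class TestErreygers:
    def test_hand_computed_toys(self, design):
        ranks = np.array([0.125, 0.375, 0.625, 0.875])
        df = frame(4, ranks)
        e1 = erreygers_ci([0, 0, 1, 1], df["rank"], df, design, n_boot=0)
        assert e1.point == pytest.approx(1.0)
        e2 = erreygers_ci([0, 1, 0, 1], df["rank"], df, design, n_boot=0)
        assert e2.point == pytest.approx(0.5)

    def test_constant_outcome_zero(self, design):
        df = frame(4, np.array([0.125, 0.375, 0.625, 0.875]))
        e = erreygers_ci([1, 1, 1, 1], df["rank"], df, design, n_boot=0)
        assert e.point == pytest.approx(0.0)

    def test_constant_ranks_rejected(self, design):
        df = frame(4, np.full(4, 0.5))
        with pytest.raises(ValueError, match="constant"):
            erreygers_ci([0, 1, 0, 1], df["rank"], df, design, n_boot=0)

    def test_rank_reversal_antisymmetry_and_bound(self, design):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(10, 101)
            r = weighted_fractional_rank(
                pd.Series(rng.choice(list("abcde"), n)),
                np.ones(n),
            )
            y = rng.integers(0, 2, n).astype(float)
            if y.min() == y.max():
                continue
            df = frame(n, r.to_numpy())
            e = erreygers_ci(y, df["rank"], df, design, n_boot=0)
            e_rev = erreygers_ci(y, 1 - df["rank"], df, design, n_boot=0)
            assert e_rev.point == pytest.approx(-e.point, abs=1e-12)
            assert abs(e.point) <= 1 + 1e-12

    def test_bootstrap_se_is_seeded(self, design):
        rng = np.random.default_rng(8)
        n = 200
        df = frame(n, rng.random(n))
        df["psu_id"] = np.repeat(np.arange(20), 10)
        y = rng.integers(0, 2, n)
        a = erreygers_ci(y, df["rank"], df, design, n_boot=50, seed=4)
        b = erreygers_ci(y, df["rank"], df, design, n_boot=50, seed=4)
        assert a.se == b.se and np.isfinite(a.se)


class TestRII:
    def test_matches_irls_oracle_on_toy(self, design):
        # unadjusted fit, equal weights, one PSU per record
        y = np.array([1, 0, 1, 1, 0, 1, 0, 0, 1, 1.0])
        r = np.array([.1, .1, .3, .3, .5, .5, .7, .7, .9, .9])
        df = frame(10, r)
        res = estimate_rii(y, df["rank"], df, design)
        X = np.column_stack([np.ones(10), r])
        beta = glm_poisson_log_oracle(y, X)
        assert res.point == pytest.approx(np.exp(beta[1]), abs=1e-6)

    def test_null_outcome_within_three_se_of_one(self, design):
        rng = np.random.default_rng(17)
        n = 50_000
        df = frame(n, np.tile([.1, .3, .5, .7, .9], n // 5))
        df["psu_id"] = np.repeat(np.arange(n // 50), 50)
        y = rng.integers(0, 2, n)
        res = estimate_rii(y, df["rank"], df, design)
        assert abs(np.log(res.point)) < 3 * res.se / res.point
        assert res.point == pytest.approx(1.0, abs=0.05)

    def test_constant_outcome_rejected(self, design):
        df = frame(4, np.array([.1, .3, .5, .7]))
        with pytest.raises(ValueError, match="constant"):
            estimate_rii(np.ones(4), df["rank"], df, design)

    def test_out_of_range_ridit_rejected(self, design):
        df = frame(3, np.array([0.0, 0.5, 0.9]))
        with pytest.raises(ValueError, match="ridit"):
            estimate_rii(np.array([0, 1, 1.0]), df["rank"], df, design)


class TestSII:
    def test_equals_wls_slope_on_balanced_toy(self, design):
        # identity-link Poisson score equations reduce to least squares here
        y = np.array([0, 0, 0, 1, 0, 1, 1, 0, 1, 1,
                      0, 1, 0, 1, 0, 1, 1, 1, 0, 1.0])
        r = np.tile([.1, .3, .5, .7, .9], 4)
        df = frame(20, r)
        res = estimate_sii(y, df["rank"], df, design)
        slope = np.polyfit(r, y, 1)[0]
        assert res.point == pytest.approx(slope, abs=0.02)

    def test_null_outcome_within_three_se_of_zero(self, design):
        rng = np.random.default_rng(23)
        n = 50_000
        df = frame(n, np.tile([.1, .3, .5, .7, .9], n // 5))
        df["psu_id"] = np.repeat(np.arange(n // 50), 50)
        y = rng.integers(0, 2, n)
        res = estimate_sii(y, df["rank"], df, design)
        assert abs(res.point) < 3 * res.se

    def test_linear_truth_recovery(self, design):
        # p = 0.3 + 0.4 r over quintile midpoints, n = 50,000
        rng = np.random.default_rng(31)
        n = 50_000
        r = np.tile([.1, .3, .5, .7, .9], n // 5)
        y = (rng.random(n) < 0.3 + 0.4 * r).astype(float)
        df = frame(n, r)
        df["psu_id"] = np.repeat(np.arange(n // 50), 50)
        res = estimate_sii(y, df["rank"], df, design)
        assert res.point == pytest.approx(0.4, abs=0.03)
        assert res.link in ("identity", "linear_probability")


class TestCrossMeasureConsistency:
    def test_erreygers_equals_scaled_slope(self, design):
        """Unadjusted, equal-size quintiles, equal weights:
        E = 8 var(r) x OLS slope; with quintile midpoints var(r) = 0.08."""
        rng = np.random.default_rng(41)
        n = 1000
        r = np.tile([.1, .3, .5, .7, .9], n // 5)
        y = (rng.random(n) < 0.2 + 0.5 * r).astype(float)
        df = frame(n, r)
        e = erreygers_ci(y, df["rank"], df, design, n_boot=0)
        slope = np.polyfit(r, y, 1)[0]
        assert np.var(r) == pytest.approx(0.08)
        assert e.point == pytest.approx(0.64 * slope, abs=1e-10)

    def test_inequality_grows_along_cascade(self, design):
        """Positive beta at every stage accumulates into a growing
        marginal RII along the cascade."""
        truth = SimulationTruth(services={"anc": (
            StageTruth(alpha=np.log(0.55), beta=0.2),
            StageTruth(alpha=np.log(0.6), beta=0.25),
            StageTruth(alpha=np.log(0.65), beta=0.3),
            StageTruth(alpha=np.log(0.7), beta=0.3),
        )})
        cfg = SimulationConfig(n_countries=1, n_strata=25,
                               clusters_per_stratum=10,
                               individuals_per_cluster=200, seed=51,
                               eligibility_fraction={"anc": 1.0})
        df = generate_survey(cfg, truth)
        r = weighted_fractional_rank(df["wealth_quintile"], df["weight"])
        riis = []
        for stage in ("contact", "crude", "quality", "adherence"):
            res = estimate_rii(df[f"anc_{stage}"], r, df, design)
            riis.append(res.point)
        assert all(a < b for a, b in zip(riis, riis[1:]))


class TestVIF:
    def test_orthogonal_covariates(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        assert np.allclose(vif(X), 1.0)

    def test_correlated_pair_closed_form(self):
        # correlation 0.8 -> VIF = 1/(1-0.64) = 2.78 for both
        rng = np.random.default_rng(3)
        n = 20_000
        a = rng.normal(size=n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=n)
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert out["a"] == pytest.approx(1 / (1 - 0.64), rel=0.05)
        assert out["b"] == pytest.approx(out["a"])

    def test_duplicated_column_flagged_infinite(self):
        X = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [1, 2, 3, 4.0],
                          "c": [0, 1, 0, 1.0]})
        out = vif(X)
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vif(pd.DataFrame({"a": [1, 1, 1.0], "b": [0, 1, 0.0]}))
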