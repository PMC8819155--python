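"""Closed-form checks of the GLM engine, adjusted Wald test, Tobit MLE,
and change-score mediation."""

import numpy as np
import pandas as pd
import pytest

from normproxy import estimators
from normproxy.datamodel import Domain, ParameterError, SurveySchema, SurveyTable
from normproxy.estimators import (
    EstimationError,
    adjusted_wald,
    mediate_change_scores,
    tobit,
    weighted_glm,
)


def _table(df, **schema_kw):
    return SurveyTable(df, SurveySchema(**schema_kw), check=False)


def _two_by_two(n1, e1, n0, e0):
    """exposed group with e1/n1 events, unexposed with e0/n0."""
    rows = []
    for i in range(n1):
        rows.append((f"e{i}", f"c{i % 10}", 1.0, 1, int(i < e1)))
    for i in range(n0):
        rows.append((f"u{i}", f"c{i % 10}", 1.0, 0, int(i < e0)))
    return pd.DataFrame(rows, columns=["person_id", "cluster_id", "weight",
                                       "x", "y"])


class TestWeightedGLM:
    def test_logistic_closed_form_log_odds_ratio(self):
        t = _table(_two_by_two(100, 30, 100, 10), weight="weight")
        fit = weighted_glm(t, "y", ["x"], family="logistic")
        want = np.log((30 * 90) / (70 * 10))
        assert fit.coefficients["x"] == pytest.approx(want, abs=1e-6)

    def test_poisson_closed_form_grouped_mle(self, rng):
        n = 200
        x = rng.integers(0, 2, n)
        y = np.where(x == 1, rng.poisson(3.0, n), rng.poisson(1.5, n))
        df = pd.DataFrame({"person_id": [str(i) for i in range(n)],
                           "cluster_id": "c0", "x": x, "y": y})
        fit = weighted_glm(_table(df), "y", ["x"], family="poisson")
        want = np.log(y[x == 1].mean() / y[x == 0].mean())
        assert fit.coefficients["x"] == pytest.approx(want, abs=1e-8)

    def test_constant_outcome_degenerate(self):
        df = _two_by_two(20, 0, 20, 0)
        fit = weighted_glm(_table(df, weight="weight"), "y", ["x"])
        assert not fit.converged
        assert any("inestimable" in f for f in fit.flags)

    def test_weights_replicate_frequency(self):
        # weight-2 rows behave like duplicated rows for the point estimate
        base = _two_by_two(50, 20, 50, 10)
        dup = pd.concat([base, base[base["x"] == 1]], ignore_index=True)
        dup["person_id"] = [f"r{i}" for i in range(len(dup))]
        wt = base.copy()
        wt.loc[wt["x"] == 1, "weight"] = 2.0
        f_dup = weighted_glm(_table(dup, weight="weight"), "y", ["x"])
        f_wt = weighted_glm(_table(wt, weight="weight"), "y", ["x"])
        assert f_dup.coefficients["x"] == pytest.approx(f_wt.coefficients["x"],
                                                        abs=1e-8)

    def test_singleton_clusters_match_hc0(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.7 * x)))).astype(int)
        df = pd.DataFrame({"person_id": [str(i) for i in range(n)],
                           "cluster_id": [str(i) for i in range(n)],
                           "x": x, "y": y})
        fit = weighted_glm(_table(df), "y", ["x"])
        import statsmodels.api as sm
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()
                     ).fit(cov_type="HC0")
        assert fit.se["x"] == pytest.approx(ref.bse[1], rel=1e-4)

    def test_irls_oracle_on_small_fixture(self, rng):
        # independent IRLS loop written here, checked to 1e-8
        n = 50
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 0.5).astype(int)
        df = pd.DataFrame({"person_id": [str(i) for i in range(n)],
                           "cluster_id": "c", "x": x, "y": y})
        fit = weighted_glm(_table(df), "y", ["x"])
        X = np.column_stack([np.ones(n), x])
        beta = np.zeros(2)
        for _ in range(100):
            mu = 1 / (1 + np.exp(-X @ beta))
            W = mu * (1 - mu)
            z = X @ beta + (y - mu) / W
            beta_new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
            if np.max(np.abs(beta_new - beta)) < 1e-12:
                beta = beta_new
                break
            beta = beta_new
        assert fit.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.coefficients["x"] == pytest.approx(beta[1], abs=1e-8)

    def test_collinear_term_dropped_and_reported(self, rng):
        n = 100
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 0.4).astype(int)
        df = pd.DataFrame({"person_id": [str(i) for i in range(n)],
                           "cluster_id": "c", "x": x, "x2": 2 * x, "y": y})
        fit = weighted_glm(_table(df), "y", ["x", "x2"])
        assert "x2" in fit.dropped_terms


class TestAdjustedWald:
    def _grouped(self, props, clusters_per_group=4, n_per_cluster=25, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, p in enumerate(props):
            for c in range(clusters_per_group):
                for i in range(n_per_cluster):
                    rows.append((f"g{g}c{c}i{i}", f"g{g}c{c}", f"g{g}", 1.0,
                                 int(rng.random() < p)))
        df = pd.DataFrame(rows, columns=["person_id", "cluster_id", "group",
                                         "weight", "y"])
        return _table(df, weight="weight")

    def test_identical_groups(self):
        t = self._grouped([0.3, 0.3], seed=1)
        df = t.df.copy()
        df.loc[df["group"] == "g1", "y"] = df.loc[df["group"] == "g0", "y"].to_numpy()
        res = adjusted_wald(_table(df, weight="weight"), "y", "group")
        assert res["diff"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_single_cluster_group_rejected(self):
        t = self._grouped([0.3, 0.5], clusters_per_group=1)
        with pytest.raises(EstimationError):
            adjusted_wald(t, "y", "group")

    def test_brute_force_between_cluster_variance(self):
        t = self._grouped([0.2, 0.6], clusters_per_group=4, seed=2)
        res = adjusted_wald(t, "y", "group")
        df = t.df
        ses = []
        for g in ("g0", "g1"):
            sub = df[df["group"] == g]
            W = sub["weight"].sum()
            p = (sub["weight"] * sub["y"]).sum() / W
            z = []
            for c in sub["cluster_id"].unique():
                cc = sub[sub["cluster_id"] == c]
                z.append(((cc["y"] - p) * cc["weight"]).sum())
            k = len(z)
            ses.append(k / (k - 1) * sum(v**2 for v in z) / W**2)
        assert res["se"] == pytest.approx(np.sqrt(sum(ses)), abs=1e-12)

    def test_null_type_one_error(self):
        rejections = 0
        n_sims = 100
        for seed in range(n_sims):
            t = self._grouped([0.4, 0.4], clusters_per_group=8,
                              n_per_cluster=20, seed=seed)
            rejections += adjusted_wald(t, "y", "group")["p"] < 0.05
        assert rejections <= 12  # ~5% nominal


class TestTobit:
    def _sim(self, n, seed, upper=3.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        ystar = 1 + 2 * x + rng.normal(0, 1, n)
        df = pd.DataFrame({"person_id": [str(i) for i in range(n)],
                           "cluster_id": "c", "x": x,
                           "y": np.minimum(ystar, upper)})
        sch = SurveySchema(outcomes={"y": Domain("real", lo=-100, hi=upper)})
        return SurveyTable(df, sch, check=False), ystar

    def test_uncensored_reduces_to_ols(self):
        t, ystar = self._sim(400, 41, upper=1e9)
        fit = tobit(t, "y", ["x"], censoring="right", bounds=(-1e9, 1e9))
        X = np.column_stack([np.ones(len(ystar)), t.df["x"]])
        b, *_ = np.linalg.lstsq(X, ystar, rcond=None)
        assert fit.coefficients["intercept"] == pytest.approx(b[0], abs=1e-6)
        assert fit.coefficients["x"] == pytest.approx(b[1], abs=1e-6)

    def test_right_censored_recovery(self):
        t, _ = self._sim(2000, 42)
        fit = tobit(t, "y", ["x"], censoring="right")
        assert fit.converged
        assert fit.coefficients["intercept"] == pytest.approx(1.0, rel=0.05)
        assert fit.coefficients["x"] == pytest.approx(2.0, rel=0.05)
        assert fit.sigma == pytest.approx(1.0, rel=0.05)

    def test_moderation_interaction_recovery(self):
        rng = np.random.default_rng(43)
        n = 1500
        x = rng.normal(0, 1, n)
        z = rng.integers(0, 2, n)
        ystar = 0.5 + 1.0 * x + 0.3 * z + 0.5 * x * z + rng.normal(0, 1, n)
        hi = np.quantile(ystar, 0.85)
        df = pd.DataFrame({"person_id": [str(i) for i in range(n)],
                           "cluster_id": "c", "x": x, "z": z,
                           "y": np.minimum(ystar, hi)})
        sch = SurveySchema(outcomes={"y": Domain("real", lo=-100, hi=hi)})
        fit = tobit(SurveyTable(df, sch, check=False), "y",
                    ["x", "z", "x:z"], censoring="right")
        assert fit.coefficients["x:z"] == pytest.approx(0.5, abs=0.15)

    def test_all_censored_rejected(self):
        t, _ = self._sim(50, 44)
        df = t.df.copy()
        df["y"] = 3.0
        with pytest.raises(EstimationError):
            tobit(SurveyTable(df, t.schema, check=False), "y", ["x"],
                  censoring="right")

    def test_undeclared_bounds_rejected(self):
        t, _ = self._sim(50, 45)
        with pytest.raises(ParameterError):
            tobit(t, "x", ["y"])  # x has no declared bounds


class TestMediation:
    def _sim(self, n, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        m = a * x + rng.normal(0, 1, n)
        y = b * m + rng.normal(0, 1, n)
        df = pd.DataFrame({"person_id": [str(i) for i in range(n)],
                           "cluster_id": "c", "dx": x, "dm": m, "dy": y})
        return _table(df)

    def test_exact_linear_decomposition(self):
        t = self._sim(200, 0.6, 0.5, 51)
        r = mediate_change_scores(t, "dy", "dx", "dm", n_boot=100, seed=1)
        assert r.c - (r.c_prime + r.indirect) == pytest.approx(0.0, abs=1e-8)
        assert r.indirect == pytest.approx(r.a * r.b, abs=1e-14)

    def test_full_mediation_recovery(self):
        t = self._sim(4000, 0.6, 0.5, 52)
        r = mediate_change_scores(t, "dy", "dx", "dm", n_boot=200, seed=2)
        assert r.indirect == pytest.approx(0.30, abs=0.05)
        assert abs(r.c_prime) < 0.06

    def test_null_ci_covers_zero(self):
        t = self._sim(500, 0.0, 0.5, 53)
        r = mediate_change_scores(t, "dy", "dx", "dm", n_boot=300, seed=3)
        assert r.indirect_ci[0] <= 0.0 <= r.indirect_ci[1]

    def test_bootstrap_seed_determinism(self):
        t = self._sim(200, 0.4, 0.4, 54)
        r1 = mediate_change_scores(t, "dy", "dx", "dm", n_boot=150, seed=9)
        r2 = mediate_change_scores(t, "dy", "dx", "dm", n_boot=150, seed=9)
        assert r1.indirect_ci == r2.indirect_ci

    def test_moderated_conditional_effects(self, rng):
        n = 2000
        x = rng.normal(0, 1, n)
        w = rng.normal(0, 1, n)
        m = (0.5 + 0.4 * w) * x + rng.normal(0, 1, n)
        y = 0.5 * m + rng.normal(0, 1, n)
        df = pd.DataFrame({"person_id": [str(i) for i in range(n)],
                           "cluster_id": "c", "dx": x, "dm": m, "dy": y,
                           "wealth": w})
        r = mediate_change_scores(_table(df), "dy", "dx", "dm",
                                  moderator="wealth", n_boot=100, seed=4)
        assert (r.conditional_indirect["mean_plus_sd"]
                > r.conditional_indirect["mean_minus_sd"])

    def test_zero_variance_mediator_rejected(self):
        t = self._sim(100, 0.5, 0.5, 55)
        t.df["dm"] = 1.0
        with pytest.raises(EstimationError):
            mediate_change_scores(t, "dy", "dx", "dm", n_boot=100, seed=5)

    def test_too_few_bootstraps_rejected(self):
        t = self._sim(100, 0.5, 0.5, 56)
        with pytest.raises(ParameterError):
            mediate_change_scores(t, "dy", "dx", "dm", n_boot=50, seed=6)
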