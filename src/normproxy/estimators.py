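"""Shared statistical engines: weighted GLMs with cluster-robust errors,
design-adjusted Wald tests, censored-normal (Tobit) regression, and
change-score mediation with percentile-bootstrap inference.

Cluster-robust variances default to the CR0 sandwich (no small-sample
correction); CR1 finite-cluster scaling is available via ``cr``.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .datamodel import ParameterError, SurveyTable

Z95 = 1.959963984540054  # standard normal 97.5% quantile


class EstimationError(ValueError):
    pass


@dataclasses.dataclass
class FitResult:
    """Coefficients and cluster-robust standard errors of one model fit."""

    coefficients: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    n_obs: int
    n_clusters: int
    converged: bool
    model: str
    sigma: float | None = None  # tobit residual scale
    dropped_terms: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    @classmethod
    def from_arrays(cls, names: Sequence[str], beta: np.ndarray, se: np.ndarray,
                    n_obs: int, n_clusters: int, converged: bool, model: str,
                    crit: float = Z95, **kw: Any) -> "FitResult":
        coef = {n: float(b) for n, b in zip(names, beta)}
        ses = {n: float(s) for n, s in zip(names, se)}
        ci = {n: (coef[n] - crit * ses[n], coef[n] + crit * ses[n]) for n in coef}
        return cls(coef, ses, ci, n_obs, n_clusters, converged, model, **kw)


@dataclasses.dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    indirect_ci: tuple[float, float]
    n_boot: int
    conditional_indirect: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# Design-matrix assembly


def _design_matrix(df: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Build [1, terms...] allowing ``a:b`` product terms."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for t in terms:
        if ":" in t:
            parts = t.split(":")
            v = np.ones(len(df))
            for p in parts:
                v = v * pd.to_numeric(df[p], errors="coerce").to_numpy(float)
        else:
            v = pd.to_numeric(df[t], errors="coerce").to_numpy(float)
        cols.append(v)
        names.append(t)
    return np.column_stack(cols), names


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedy rank filter keeping the leftmost independent columns."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        cand = keep + [j]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            keep.append(j)
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def _cluster_sandwich(score: np.ndarray, bread_inv: np.ndarray,
                      clusters: np.ndarray, cr: str) -> np.ndarray:
    """CR0/CR1 sandwich from per-observation score contributions."""
    meat = np.zeros((score.shape[1], score.shape[1]))
    for g in np.unique(clusters):
        s = score[clusters == g].sum(axis=0)
        meat += np.outer(s, s)
    V = bread_inv @ meat @ bread_inv
    if cr == "CR1":
        G = len(np.unique(clusters))
        V *= G / (G - 1) if G > 1 else 1.0
    return V


# ---------------------------------------------------------------------------
# Weighted GLM


def weighted_glm(table: SurveyTable, outcome: str, terms: Sequence[str],
                 family: str = "logistic", cluster_var: str | None = None,
                 weighted: bool = True, cr: str = "CR0") -> FitResult:
    """Weighted logistic or Poisson ML fit with cluster-robust errors.

    Rows with a missing outcome, term, or cluster are dropped listwise.
    Collinear columns are dropped (reported in ``dropped_terms``).
    Perfect separation or non-convergence yields ``converged=False``.

    ``cr`` chooses the clustered variance: CR0 (plain sandwich, default),
    CR1 (G/(G-1) scaling), or CR3 (delete-one-cluster jackknife).  With
    few clusters the sandwich forms understate sampling variance; CR3
    with its t(G-1) confidence intervals stays close to nominal coverage
    and is what the taboo-gap model uses (strata are typically few).
    """
    if family not in ("logistic", "poisson"):
        raise ParameterError(f"unknown family {family!r}")
    if cr not in ("CR0", "CR1", "CR3"):
        raise ParameterError(f"cr must be CR0, CR1 or CR3, got {cr!r}")
    df = table.df
    cluster_var = cluster_var or table.schema.cluster_id
    used = [outcome, cluster_var] + [p for t in terms for p in t.split(":")]
    sub = df[sorted(set(used))].copy()
    sub["_w"] = table.weights.to_numpy(float) if weighted else 1.0
    sub = sub.dropna()
    if sub.empty:
        raise EstimationError("no complete rows for GLM fit")
    y = pd.to_numeric(sub[outcome]).to_numpy(float)
    w = sub["_w"].to_numpy(float)
    clusters = sub[cluster_var].to_numpy()
    X, names = _design_matrix(sub, terms)

    flags: list[str] = []
    if np.ptp(y) == 0:
        # degenerate constant outcome: intercept-only answer, slopes inestimable
        beta = np.full(X.shape[1], np.nan)
        beta[0] = (np.log(y[0] / (1 - y[0])) if family == "logistic" and 0 < y[0] < 1
                   else (np.inf if y[0] > 0 else -np.inf))
        if family == "poisson":
            beta[0] = np.log(y[0]) if y[0] > 0 else -np.inf
        se = np.full(X.shape[1], np.nan)
        return FitResult.from_arrays(names, beta, se, len(y),
                                     len(np.unique(clusters)), False, family,
                                     flags=("inestimable: constant outcome",))

    X, names, dropped = _drop_collinear(X, names)
    fam = sm.families.Binomial() if family == "logistic" else sm.families.Poisson()
    converged = True
    try:
        with np.errstate(all="ignore"):
            model = sm.GLM(y, X, family=fam, freq_weights=w)
            res = model.fit(maxiter=200, tol=1e-8)
        beta = np.asarray(res.params)
        converged = bool(res.converged)
        mu = np.asarray(res.fittedvalues)
    except Exception as exc:  # separation and friends
        raise EstimationError(f"GLM fit failed: {exc}") from exc

    if family == "logistic" and (np.max(np.abs(beta)) > 30 or np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10)):
        if np.max(np.abs(beta[1:])) > 15:
            converged = False
            flags.append("possible separation: extreme coefficients")

    G = len(np.unique(clusters))
    crit = Z95
    if cr == "CR3":
        # delete-one-cluster jackknife, warm-started at the full fit
        betas = []
        for g in np.unique(clusters):
            m = clusters != g
            with np.errstate(all="ignore"):
                betas.append(sm.GLM(y[m], X[m], family=fam,
                                    freq_weights=w[m]).fit(
                    start_params=beta, maxiter=200, tol=1e-8).params)
        B = np.asarray(betas)
        Bc = B - B.mean(axis=0)
        V = (G - 1) / G * Bc.T @ Bc
        crit = float(scipy.stats.t.ppf(0.975, G - 1)) if G > 1 else Z95
    else:
        # CR0/CR1 sandwich from weighted score contributions
        if family == "logistic":
            Winfo = w * mu * (1 - mu)
        else:
            Winfo = w * mu
        score = (w * (y - mu))[:, None] * X
        info = X.T @ (Winfo[:, None] * X)
        try:
            bread_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            bread_inv = np.linalg.pinv(info)
        V = _cluster_sandwich(score, bread_inv, clusters, cr)
    se = np.sqrt(np.clip(np.diag(V), 0, None))
    return FitResult.from_arrays(names, beta, se, len(y), G, converged, family,
                                 crit=crit, dropped_terms=tuple(dropped),
                                 flags=tuple(flags))


# ---------------------------------------------------------------------------
# Adjusted Wald comparison of two weighted proportions


def adjusted_wald(table: SurveyTable, proportion_var: str, group_var: str,
                  cluster_var: str | None = None, weighted: bool = True) -> dict[str, float]:
    """Design-based comparison of a weighted proportion across two groups.

    The variance of each group's weighted proportion is estimated from
    between-cluster variation of weighted residual totals, the standard
    Taylor-linearised form for a ratio mean under cluster sampling.
    """
    cluster_var = cluster_var or table.schema.cluster_id
    df = table.df[[proportion_var, group_var, cluster_var]].copy()
    df["_w"] = table.weights.to_numpy(float) if weighted else 1.0
    df = df.dropna()
    groups = sorted(df[group_var].unique())
    if len(groups) != 2:
        raise ParameterError(f"group_var must have exactly 2 levels, got {groups}")
    stats = {}
    for g in groups:
        sub = df[df[group_var] == g]
        k = sub[cluster_var].nunique()
        if k < 2:
            raise EstimationError(f"group {g!r} has a single cluster; variance undefined")
        y = pd.to_numeric(sub[proportion_var]).to_numpy(float)
        w = sub["_w"].to_numpy(float)
        W = w.sum()
        p = float(np.sum(w * y) / W)
        # cluster totals of weighted residuals
        resid = w * (y - p)
        z = pd.Series(resid).groupby(sub[cluster_var].to_numpy()).sum().to_numpy()
        var = k / (k - 1) * float(np.sum(z**2)) / W**2
        stats[g] = (p, var)
    (p1, v1), (p2, v2) = stats[groups[0]], stats[groups[1]]
    diff = p1 - p2
    se = float(np.sqrt(v1 + v2))
    z = diff / se if se > 0 else 0.0
    p = float(2 * scipy.stats.norm.sf(abs(z)))
    return {"diff": float(diff), "se": se, "z": float(z), "p": min(p, 1.0),
            "groups": tuple(groups), "props": (p1, p2)}


# ---------------------------------------------------------------------------
# Tobit (censored-normal) regression


def _tobit_negll_rows(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                      left: float | None, right: float | None) -> np.ndarray:
    beta, logsig = params[:-1], params[-1]
    sig = np.exp(logsig)
    xb = X @ beta
    ll = np.zeros(len(y))
    interior = np.ones(len(y), dtype=bool)
    if left is not None:
        at_l = y <= left
        interior &= ~at_l
        if at_l.any():
            ll[at_l] = scipy.stats.norm.logcdf((left - xb[at_l]) / sig)
    if right is not None:
        at_r = y >= right
        interior &= ~at_r
        if at_r.any():
            ll[at_r] = scipy.stats.norm.logsf((right - xb[at_r]) / sig)
    if interior.any():
        z = (y[interior] - xb[interior]) / sig
        ll[interior] = scipy.stats.norm.logpdf(z) - logsig
    return -ll


def _tobit_negll(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                 left: float | None, right: float | None) -> float:
    return float(_tobit_negll_rows(params, X, y, left, right).sum())


def _tobit_grad(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                left: float | None, right: float | None) -> np.ndarray:
    """Analytic gradient of the negative censored-normal log-likelihood
    in (beta, log sigma)."""
    beta, logsig = params[:-1], params[-1]
    sig = np.exp(logsig)
    xb = X @ beta
    dbeta_fac = np.zeros(len(y))  # d ll / d xb, times sigma
    dlogsig = np.zeros(len(y))
    interior = np.ones(len(y), dtype=bool)
    if left is not None:
        at_l = y <= left
        interior &= ~at_l
        if at_l.any():
            z = (left - xb[at_l]) / sig
            # inverse Mills ratio phi/Phi, computed in log space for stability
            r = np.exp(scipy.stats.norm.logpdf(z) - scipy.stats.norm.logcdf(z))
            dbeta_fac[at_l] = -r
            dlogsig[at_l] = -r * z
    if right is not None:
        at_r = y >= right
        interior &= ~at_r
        if at_r.any():
            z = (right - xb[at_r]) / sig
            r = np.exp(scipy.stats.norm.logpdf(z) - scipy.stats.norm.logsf(z))
            dbeta_fac[at_r] = r
            dlogsig[at_r] = r * z
    if interior.any():
        z = (y[interior] - xb[interior]) / sig
        dbeta_fac[interior] = z
        dlogsig[interior] = z**2 - 1
    g_beta = X.T @ (dbeta_fac / sig)
    return -np.concatenate([g_beta, [dlogsig.sum()]])


def tobit(table: SurveyTable, outcome: str, terms: Sequence[str],
          censoring: str = "both", bounds: tuple[float, float] | None = None,
          cluster_var: str | None = None, cr: str = "CR0") -> FitResult:
    """Censored-normal MLE: latent y* = Xb + e, e ~ N(0, s^2), y clipped
    at the outcome's declared bounds.

    ``bounds`` defaults to the outcome's declared [lo, hi] in the schema.
    ``censoring`` selects which bound(s) generate probability mass.
    Interaction (moderation) terms are written ``a:b``.
    """
    if censoring not in ("left", "right", "both"):
        raise ParameterError(f"censoring must be left/right/both, got {censoring!r}")
    if bounds is None:
        dom = table.schema.outcomes.get(outcome) or table.schema.items.get(outcome)
        if dom is None or dom.lo is None or dom.hi is None:
            raise ParameterError(
                f"outcome {outcome!r} has no declared [lo, hi]; pass bounds=")
        bounds = (float(dom.lo), float(dom.hi))
    left = bounds[0] if censoring in ("left", "both") else None
    right = bounds[1] if censoring in ("right", "both") else None

    cluster_var = cluster_var or table.schema.cluster_id
    used = [outcome, cluster_var] + [p for t in terms for p in t.split(":")]
    sub = table.df[sorted(set(used))].dropna()
    y = pd.to_numeric(sub[outcome]).to_numpy(float)
    clusters = sub[cluster_var].to_numpy()
    X, names = _design_matrix(sub, terms)
    X, names, dropped = _drop_collinear(X, names)

    uncensored = np.ones(len(y), bool)
    if left is not None:
        uncensored &= y > left
    if right is not None:
        uncensored &= y < right
    if not uncensored.any():
        raise EstimationError("all observations censored; Tobit inestimable")

    # OLS start values
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta0
    sig0 = max(float(np.std(resid0)), 1e-3)
    x0 = np.concatenate([beta0, [np.log(sig0)]])
    opt = scipy.optimize.minimize(
        _tobit_negll, x0, args=(X, y, left, right), jac=_tobit_grad,
        method="BFGS", options={"maxiter": 500})
    beta = opt.x[:-1]
    sigma = float(np.exp(opt.x[-1]))
    gmax = float(np.max(np.abs(_tobit_grad(opt.x, X, y, left, right))))
    converged = (bool(opt.success) or gmax < 1e-5 * max(1.0, len(y))) \
        and sigma > 1e-6

    # observed-information SEs for beta (delta method leaves logsig block out)
    import statsmodels.tools.numdiff as nd
    H = nd.approx_hess1(opt.x, _tobit_negll, args=(X, y, left, right))
    try:
        Vfull = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        Vfull = np.linalg.pinv(H)
    if cluster_var is not None and len(np.unique(clusters)) > 1:
        # cluster sandwich over per-row score contributions
        score = nd.approx_fprime(
            opt.x, lambda p: _tobit_negll_rows(p, X, y, left, right))
        V = _cluster_sandwich(score, Vfull, clusters, cr)
    else:
        V = Vfull
    se = np.sqrt(np.clip(np.diag(V)[:-1], 0, None))
    res = FitResult.from_arrays(names, beta, se, len(y),
                                len(np.unique(clusters)), converged, "tobit",
                                sigma=sigma, dropped_terms=tuple(dropped))
    if sigma <= 1e-6:
        res.flags = ("sigma collapsed toward 0",)
    return res


# ---------------------------------------------------------------------------
# Change-score mediation


def _ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    return b


def mediate_change_scores(table: SurveyTable, outcome_change: str,
                          predictor_change: str, mediator_change: str,
                          covariates: Sequence[str] = (),
                          moderator: str | None = None,
                          n_boot: int = 1000, seed: int = 0) -> MediationResult:
    """Product-of-coefficients mediation on change scores.

    a-path: mediator ~ predictor (+ covariates); b-path: outcome ~
    mediator + predictor (+ covariates); indirect = a*b with a percentile
    bootstrap CI.  With a moderator, both paths gain predictor x moderator
    and mediator x moderator interactions and conditional indirect effects
    are reported at moderator mean +/- 1 sd.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    cols = [outcome_change, predictor_change, mediator_change, *covariates]
    if moderator:
        cols.append(moderator)
    sub = table.df[sorted(set(cols))].dropna().reset_index(drop=True)
    if sub[mediator_change].std() == 0:
        raise EstimationError("mediator has zero variance")
    y = sub[outcome_change].to_numpy(float)
    x = sub[predictor_change].to_numpy(float)
    m = sub[mediator_change].to_numpy(float)
    C = (sub[list(covariates)].to_numpy(float)
         if covariates else np.empty((len(sub), 0)))
    ones = np.ones((len(sub), 1))

    if moderator:
        w = sub[moderator].to_numpy(float)
        Xa = np.column_stack([ones, x, w, x * w, C])
        Xb = np.column_stack([ones, m, x, w, m * w, C])

        def paths(yv, xv, mv, wv, Cv):
            o = np.ones((len(yv), 1))
            ba = _ols_beta(np.column_stack([o, xv, wv, xv * wv, Cv]), mv)
            bb = _ols_beta(np.column_stack([o, mv, xv, wv, mv * wv, Cv]), yv)
            bc = _ols_beta(np.column_stack([o, xv, wv, xv * wv, Cv]), yv)
            return ba, bb, bc

        ba, bb, bc = paths(y, x, m, w, C)
        a, b = float(ba[1]), float(bb[1])
        c, c_prime = float(bc[1]), float(bb[2])
        mu, sd = float(w.mean()), float(w.std())
        cond = {}
        for label, wv in (("mean_minus_sd", mu - sd), ("mean", mu), ("mean_plus_sd", mu + sd)):
            a_w = ba[1] + ba[3] * wv
            b_w = bb[1] + bb[4] * wv
            cond[label] = float(a_w * b_w)
    else:
        Xa = np.column_stack([ones, x, C])
        Xb = np.column_stack([ones, m, x, C])
        Xc = np.column_stack([ones, x, C])
        ba = _ols_beta(Xa, m)
        bb = _ols_beta(Xb, y)
        bc = _ols_beta(Xc, y)
        a, b = float(ba[1]), float(bb[1])
        c, c_prime = float(bc[1]), float(bb[2])
        cond = None

    rng = np.random.default_rng(seed)
    n = len(sub)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        yi, xi, mi, Ci = y[idx], x[idx], m[idx], C[idx]
        o = np.ones((n, 1))
        if moderator:
            wi = w[idx]
            bai = _ols_beta(np.column_stack([o, xi, wi, xi * wi, Ci]), mi)
            bbi = _ols_beta(np.column_stack([o, mi, xi, wi, mi * wi, Ci]), yi)
        else:
            bai = _ols_beta(np.column_stack([o, xi, Ci]), mi)
            bbi = _ols_beta(np.column_stack([o, mi, xi, Ci]), yi)
        boot[i] = bai[1] * bbi[1]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return MediationResult(a=a, b=b, c=c, c_prime=c_prime, indirect=a * b,
                           indirect_ci=(float(lo), float(hi)), n_boot=n_boot,
                           conditional_indirect=cond)
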