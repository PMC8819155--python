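"""One-way ANOVA intraclass correlation for screening attitudes and
behaviours for normative clustering.

The ICC here is the classic one-way random-effects estimator
rho = (MSB - MSW) / (MSB + (n0 - 1) MSW) with effective cluster size
n0 = (N - sum n_j^2 / N) / (K - 1).  Binary variables are treated as
0/1 reals.  Weights are deliberately ignored (unweighted ANOVA): no
weighted variant is defined for this estimator, and the module reports
magnitudes only — it never issues a "norm present" verdict, since no
accepted ICC threshold for normative clustering exists.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ParameterError, SurveyTable
from .estimators import EstimationError, Z95


@dataclasses.dataclass
class ICCResult:
    rho_hat: float
    msb: float
    msw: float
    n0: float
    k: int
    n_total: int
    ci: tuple[float, float] | None = None
    flag: str | None = None


def anova_icc(values: Sequence[float], cluster_ids: Sequence,
              ci: bool = False) -> ICCResult:
    """One-way random-effects ANOVA ICC with optional large-sample CI.

    Missing values must be removed beforehand; requires >= 2 clusters and
    at least one cluster with >= 2 observations.  All-identical values
    yield rho_hat = 0 flagged "degenerate".  The optional CI uses the
    large-sample (Smith-type) variance approximation at the effective
    balanced cluster size n0.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(cluster_ids)
    if len(y) != len(g):
        raise ParameterError("values and cluster_ids must be parallel")
    if np.isnan(y).any():
        raise ParameterError("remove missing values before calling anova_icc")
    labels, inv = np.unique(g, return_inverse=True)
    K = len(labels)
    if K < 2:
        raise EstimationError("ICC requires at least 2 clusters")
    n_j = np.bincount(inv).astype(float)
    if (n_j < 1).any() or (n_j >= 2).sum() < 1:
        raise EstimationError("need every cluster non-empty and one with >= 2 rows")
    N = float(len(y))
    n0 = (N - float(np.sum(n_j**2)) / N) / (K - 1)

    grand = y.mean()
    means = np.bincount(inv, weights=y) / n_j
    ssb = float(np.sum(n_j * (means - grand) ** 2))
    ssw = float(np.sum((y - means[inv]) ** 2))
    msb = ssb / (K - 1)
    msw = ssw / (N - K) if N > K else 0.0

    if ssb == 0.0 and ssw == 0.0:
        return ICCResult(0.0, 0.0, 0.0, n0, K, int(N), flag="degenerate")
    denom = msb + (n0 - 1) * msw
    rho = (msb - msw) / denom if denom != 0 else 0.0
    res = ICCResult(float(rho), msb, msw, n0, K, int(N))
    if ci:
        # large-sample variance at balanced n0 (Smith 1956 approximation)
        var = (2 * (1 - rho) ** 2 * (1 + (n0 - 1) * rho) ** 2
               / (n0 * (n0 - 1) * (K - 1)))
        half = Z95 * np.sqrt(var)
        lo = max(rho - half, -1.0 / (n0 - 1))
        res.ci = (float(lo), float(min(rho + half, 1.0)))
    return res


def icc_screen(table: SurveyTable, variables: Sequence[str],
               cluster_var: str | None = None) -> list[tuple[str, ICCResult]]:
    """Per-variable ANOVA ICC, ranked descending by rho_hat.

    Variables whose preconditions fail (all missing, single cluster after
    listwise deletion) are reported with an error flag and ranked last,
    never dropped silently.  Degenerate (constant) variables rank last
    among the estimable ones.
    """
    if not variables:
        raise ParameterError("empty variable list")
    cluster_var = cluster_var or table.schema.cluster_id
    results: list[tuple[str, ICCResult]] = []
    for var in variables:
        sub = table.df[[var, cluster_var]].dropna()
        try:
            res = anova_icc(pd.to_numeric(sub[var]).to_numpy(float),
                            sub[cluster_var].to_numpy())
        except (EstimationError, ParameterError) as exc:
            res = ICCResult(float("nan"), float("nan"), float("nan"),
                            float("nan"), 0, len(sub), flag=f"error: {exc}")
        results.append((var, res))

    def key(item: tuple[str, ICCResult]) -> tuple[int, float]:
        _, r = item
        if r.flag and r.flag.startswith("error"):
            return (2, 0.0)
        if r.flag == "degenerate":
            return (1, 0.0)
        return (0, -r.rho_hat)

    return sorted(results, key=key)
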