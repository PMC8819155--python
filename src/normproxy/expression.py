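"""Gender-expression scoring by leave-one-group-out prediction of
self-reported sex from an item battery.

For each school (group), a ridge-penalised logistic regression of sex on
the items is trained on every respondent OUTSIDE that school, then used
to score the school's own respondents: a respondent's expression is the
model probability assigned to their self-reported sex, so 0.5 is
sex-atypical and values near 1 are highly gender-typical.  Peer norms
are the mean (or median) expression of same-sex peers in the same
school and grade, and the deviation measures distance from that norm.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import ParameterError, SurveyTable
from .estimators import EstimationError


@dataclasses.dataclass
class RidgeLogitModel:
    intercept: float
    coef: np.ndarray            # on the standardized item scale
    item_means: np.ndarray
    item_scales: np.ndarray
    ridge: float
    n_train: int

    def predict_proba_female(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.item_means) / self.item_scales
        return expit(self.intercept + Z @ self.coef)


@dataclasses.dataclass
class ExpressionModelSet:
    models: dict[str, RidgeLogitModel]   # held-out group -> model
    items: tuple[str, ...]
    sex_var: str
    group_var: str
    ridge: float
    n_excluded_missing: int


@dataclasses.dataclass
class ExpressionRecord:
    person_id: str
    p_female: float
    p_reported_sex: float
    expression: float
    peer_norm: float | None = None
    deviation_signed: float | None = None
    deviation_abs: float | None = None


def _fit_ridge_logit(X: np.ndarray, y: np.ndarray, ridge: float,
                     max_iter: int = 200, tol: float = 1e-10) -> tuple[float, np.ndarray]:
    """Newton-Raphson ridge logistic; intercept unpenalised.

    Minimises -loglik + (ridge/2)*||beta||^2 on already-standardised X.
    The penalty guarantees a finite optimum under perfect separation.
    """
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = expit(eta)
        grad = Xd.T @ (y - mu) - pen * beta
        W = np.clip(mu * (1 - mu), 1e-12, None)
        H = (Xd * W[:, None]).T @ Xd + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return float(beta[0]), beta[1:]


def fit_logo_models(table: SurveyTable, items: Sequence[str],
                    sex_var: str | None = None, group_var: str = "school",
                    ridge: float = 1e-3) -> ExpressionModelSet:
    """One ridge logistic model per group, trained with that group held out.

    Items are standardised on each training set; rows with any missing
    item or missing sex are excluded from both training and scoring and
    counted in ``n_excluded_missing``.  Sex F is the positive class.
    """
    if ridge <= 0:
        raise ParameterError("ridge penalty must be positive")
    sex_var = sex_var or table.schema.sex
    if not sex_var:
        raise ParameterError("no sex column declared")
    df = table.df
    cols = [sex_var, group_var, *items]
    complete = df[cols].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    sub = df.loc[complete]
    groups = sub[group_var].astype(str).unique()
    if len(groups) < 2:
        raise ParameterError("need >= 2 groups for leave-one-group-out")
    X_all = sub[list(items)].to_numpy(float)
    y_all = (sub[sex_var] == "F").to_numpy(float)
    g_all = sub[group_var].astype(str).to_numpy()
    models: dict[str, RidgeLogitModel] = {}
    for g in sorted(groups):
        train = g_all != g
        if not train.any():
            raise EstimationError(f"group {g!r} contains all rows; training set empty")
        X, y = X_all[train], y_all[train]
        means = X.mean(axis=0)
        scales = X.std(axis=0)
        scales[scales == 0] = 1.0
        Z = (X - means) / scales
        b0, b = _fit_ridge_logit(Z, y, ridge)
        models[g] = RidgeLogitModel(b0, b, means, scales, ridge, int(train.sum()))
    return ExpressionModelSet(models, tuple(items), sex_var, group_var,
                              ridge, n_excluded)


def expression_scores(table: SurveyTable,
                      models: ExpressionModelSet) -> list[ExpressionRecord]:
    """Score each respondent with their group's held-out model.

    expression = P(model assigns the respondent's self-reported sex):
    p for F respondents, 1-p for M.  Rows with missing items are skipped
    (reported via the model set's exclusion count at fit time).
    """
    df = table.df
    pid_col = table.schema.person_id
    cols = [models.sex_var, models.group_var, *models.items]
    complete = df[cols].notna().all(axis=1)
    out: list[ExpressionRecord] = []
    for g, grp in df.loc[complete].groupby(df.loc[complete, models.group_var].astype(str)):
        model = models.models.get(g)
        if model is None:
            raise ParameterError(f"no model for group {g!r}")
        X = grp[list(models.items)].to_numpy(float)
        pF = model.predict_proba_female(X)
        isF = (grp[models.sex_var] == "F").to_numpy()
        expr = np.where(isF, pF, 1 - pF)
        for pid, pf, e in zip(grp[pid_col].astype(str), pF, expr):
            out.append(ExpressionRecord(pid, float(pf), float(e), float(e)))
    return out


def peer_norms(records: Sequence[ExpressionRecord], table: SurveyTable,
               keys: tuple[str, ...] | None = None, stat: str = "mean",
               exclude_self: bool = True,
               grade_var: str = "grade") -> list[ExpressionRecord]:
    """Fill peer_norm and deviations from same-sex, same-school, same-grade
    peers.

    With exclude_self, each respondent's own score is removed from their
    cell before aggregating; singleton cells then get a missing peer norm
    (never 0).  ``stat`` is mean or median (median of an even peer set is
    the midpoint of the two central values).
    """
    if stat not in ("mean", "median"):
        raise ParameterError("stat must be mean or median")
    sch = table.schema
    if keys is None:
        if not sch.sex:
            raise ParameterError("no sex column declared")
        school = sch.group_keys[0] if sch.group_keys else "school"
        keys = (sch.sex, school, grade_var)
    df = table.df.set_index(table.df[sch.person_id].astype(str))
    by_pid = {r.person_id: r for r in records}
    cells: dict[tuple, list[str]] = {}
    for pid in by_pid:
        key = tuple(str(df.loc[pid, k]) for k in keys)
        cells.setdefault(key, []).append(pid)
    out: list[ExpressionRecord] = []
    agg = np.mean if stat == "mean" else np.median
    for pids in cells.values():
        scores = {p: by_pid[p].expression for p in pids}
        for pid in pids:
            rec = dataclasses.replace(by_pid[pid])
            peer_vals = ([v for p, v in scores.items() if p != pid]
                         if exclude_self else list(scores.values()))
            if not peer_vals:
                rec.peer_norm = None  # singleton cell: flagged missing
            else:
                rec.peer_norm = float(agg(peer_vals))
                rec.deviation_signed = rec.expression - rec.peer_norm
                rec.deviation_abs = abs(rec.deviation_signed)
            out.append(rec)
    return out


def records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
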