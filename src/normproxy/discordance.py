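"""Taboo-gap (attitude-behaviour discordance) construction and the
adolescent outcome model on it.

For a hidden, disapproved-of behaviour, the norm proxy is the per-stratum
gap between what adults do and what they say they approve of:
D_s = behaviour_s - approval_s, where behaviour is derived from ages at
first sex and first marriage and approval is one minus the weighted share
endorsing "should wait until marriage".  Adolescent outcome risk is then
modelled by Poisson regression (robust errors clustered on stratum) on
D_s in steps of 0.10, so exp(beta) is a relative risk per 10-point
increase in discordance.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import IntegrityError, ParameterError, SurveyTable
from . import estimators
from .estimators import FitResult


@dataclasses.dataclass
class DiscordanceSummary:
    stratum_id: str
    approval: float       # weighted share NOT endorsing "should wait"
    behaviour: float      # weighted share with derived premarital sex
    discordance: float    # behaviour - approval
    n_adults: int
    sex_of_adults: str    # F | M | pooled
    low_n: bool = False


def derive_premarital_behaviour(age_first_sex: float | None,
                                age_first_marriage: float | None,
                                ever_married: bool,
                                sexually_active: bool | None = None) -> float:
    """Derive the premarital-sex indicator from event ages.

    Ever-married: 1 iff first sex strictly precedes first marriage (equal
    integer-coarse ages count as NOT premarital); missing if either age is
    missing.  Never-married: the sexually_active flag decides; when that
    flag is unavailable the result is missing, never 0.
    """
    def _miss(v) -> bool:
        return v is None or (isinstance(v, float) and np.isnan(v))

    for a in (age_first_sex, age_first_marriage):
        if not _miss(a) and a < 0:
            raise IntegrityError(f"negative age {a!r}")
    if ever_married:
        if _miss(age_first_sex) or _miss(age_first_marriage):
            return float("nan")
        return 1.0 if age_first_sex < age_first_marriage else 0.0
    if sexually_active is None or (isinstance(sexually_active, float)
                                   and np.isnan(sexually_active)):
        return float("nan")
    return 1.0 if sexually_active else 0.0


def add_derived_behaviour(table: SurveyTable,
                          age_sex_var: str = "age_first_sex",
                          age_marriage_var: str = "age_first_marriage",
                          ever_married_var: str = "ever_married",
                          sexually_active_var: str | None = None,
                          out_var: str = "premarital_sex") -> SurveyTable:
    """Vectorised derive_premarital_behaviour over a table (new column)."""
    df = table.df.copy()
    sex_age = pd.to_numeric(df[age_sex_var], errors="coerce")
    mar_age = pd.to_numeric(df[age_marriage_var], errors="coerce")
    if (sex_age.dropna() < 0).any() or (mar_age.dropna() < 0).any():
        raise IntegrityError("negative age in event-age columns")
    ever = pd.to_numeric(df[ever_married_var], errors="coerce")
    active = (pd.to_numeric(df[sexually_active_var], errors="coerce")
              if sexually_active_var else pd.Series(np.nan, index=df.index))
    out = pd.Series(np.nan, index=df.index)
    married = ever == 1
    both = married & sex_age.notna() & mar_age.notna()
    out[both] = (sex_age[both] < mar_age[both]).astype(float)
    never = ever == 0
    out[never & active.notna()] = active[never & active.notna()].clip(0, 1)
    df[out_var] = out
    return SurveyTable(df, table.schema, check=False)


def stratum_discordance(table: SurveyTable, attitude_var: str,
                        stratum_var: str | None = None,
                        behaviour_var: str = "premarital_sex",
                        sex_filter: str = "pooled", weighted: bool = True,
                        low_n_floor: int = 25) -> list[DiscordanceSummary]:
    """Per-stratum approval, derived behaviour, and their gap.

    attitude_var is binary with 1 = endorses "should wait"; approval is
    1 minus its weighted mean.  The caller selects adults (age filter)
    before calling; ``sex_filter`` restricts to F or M rows.  Strata below
    ``low_n_floor`` adults are flagged low-n; empty strata are excluded.
    """
    if sex_filter not in ("F", "M", "pooled"):
        raise ParameterError("sex_filter must be F, M or pooled")
    stratum_var = stratum_var or table.schema.stratum_id or table.schema.cluster_id
    df = table.df.copy()
    df["_w"] = table.weights.to_numpy(float) if weighted else 1.0
    if sex_filter != "pooled":
        if not table.schema.sex:
            raise ParameterError("schema declares no sex column")
        df = df[df[table.schema.sex] == sex_filter]
    out: list[DiscordanceSummary] = []
    for sid, grp in df.groupby(stratum_var, sort=True):
        att = grp[[attitude_var, "_w"]].dropna()
        beh = grp[[behaviour_var, "_w"]].dropna()
        if att.empty or beh.empty:
            continue  # excluded with warning record semantics (empty stratum)
        wait_share = float(np.average(pd.to_numeric(att[attitude_var]),
                                      weights=att["_w"]))
        approval = 1.0 - wait_share
        behaviour = float(np.average(pd.to_numeric(beh[behaviour_var]),
                                     weights=beh["_w"]))
        n_adults = int(min(len(att), len(beh)))
        out.append(DiscordanceSummary(
            str(sid), approval, behaviour, behaviour - approval,
            n_adults, sex_filter, low_n=n_adults < low_n_floor))
    return out


def taboo_gap_model(adolescents: SurveyTable,
                    summaries: Sequence[DiscordanceSummary], outcome: str,
                    covariates: Sequence[str] = (), scale: float = 0.10,
                    stratum_var: str | None = None,
                    weighted: bool = True) -> FitResult:
    """Poisson model of a binary adolescent outcome on stratum discordance.

    The discordance enters in units of ``scale`` (default 0.10), so
    exp(beta) is the relative risk per 10-point widening of the taboo
    gap.  Errors are cluster-robust on stratum; because strata are
    typically few (tens, not hundreds), the jackknife (CR3) variance
    with t-based intervals is used for near-nominal coverage.  Sex
    stratification is the caller's responsibility (filter the table
    first).
    """
    stratum_var = (stratum_var or adolescents.schema.stratum_id
                   or adolescents.schema.cluster_id)
    dmap = {s.stratum_id: s.discordance for s in summaries}
    df = adolescents.df.copy()
    strata = df[stratum_var].astype(str)
    unmatched = sorted(set(strata) - set(dmap))
    if unmatched:
        raise ParameterError(f"adolescent strata without summaries: {unmatched[:5]}")
    df["discordance_step"] = strata.map(dmap).astype(float) / scale
    if df["discordance_step"].nunique() < 2:
        res = FitResult({}, {}, {}, len(df), strata.nunique(), False, "poisson",
                        flags=("inestimable: discordance constant across strata",))
        return res
    sub = SurveyTable(df, adolescents.schema, check=False)
    res = estimators.weighted_glm(
        sub, outcome, ["discordance_step", *covariates], family="poisson",
        cluster_var=stratum_var, weighted=weighted, cr="CR3")
    return res


def rr_per_step(fit: FitResult) -> tuple[float, tuple[float, float]]:
    """exp(beta) for the discordance step term, with its 95% CI."""
    b = fit.coefficients["discordance_step"]
    lo, hi = fit.ci95["discordance_step"]
    return float(np.exp(b)), (float(np.exp(lo)), float(np.exp(hi)))
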