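"""Seeded generators for survey and nomination fixtures with the
statistical structure each proxy-construction method assumes.

Every generator is a pure function of its scenario and seed: the same
call always yields the same table.  Columns prefixed ``truth_`` record
the planted generative truth for parameter-recovery tests and are never
read by analysis modules.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .datamodel import (
    Domain,
    NominationTable,
    ParameterError,
    SurveySchema,
    SurveyTable,
)


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"{name} must be a probability in [0, 1], got {p}")


# ---------------------------------------------------------------------------
# Clustered binary outcomes with controllable ICC


def gen_clustered_binary(K: int, n: int, p: float, rho: float, seed: int,
                         var: str = "y") -> SurveyTable:
    """Beta-binomial clusters whose intra-cluster correlation equals rho.

    Cluster probabilities are Beta(a, b) with a = p(1-rho)/rho and
    b = (1-p)(1-rho)/rho, whose members are Bernoulli draws; the ICC of
    this mixture is exactly rho.  rho = 0 degenerates to every cluster
    at exactly p.
    """
    if K < 2 or n < 2:
        raise ParameterError("need K >= 2 clusters of n >= 2 members")
    _check_prob("p", p)
    if not 0.0 <= rho < 1.0:
        raise ParameterError(f"rho must be in [0, 1), got {rho}")
    rng = np.random.default_rng(seed)
    if rho == 0.0:
        cluster_p = np.full(K, p)
    else:
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        cluster_p = rng.beta(a, b, size=K)
    y = rng.random((K, n)) < cluster_p[:, None]
    df = pd.DataFrame({
        "person_id": [f"p{i:06d}" for i in range(K * n)],
        "cluster_id": np.repeat([f"c{j:04d}" for j in range(K)], n),
        var: y.ravel().astype(int),
        "truth_cluster_p": np.repeat(cluster_p, n),
    })
    schema = SurveySchema(items={var: Domain("binary")})
    return SurveyTable(df, schema, check=False)


# ---------------------------------------------------------------------------
# Case study 1: sanctions for counter-normative labour participation


@dataclasses.dataclass
class SanctionScenario:
    """Two-regime communities: in restrictive (low-FLP) clusters, women who
    do participate in the labour force face extra IPV risk."""

    K: int = 150
    n: int = 40
    restrictive_frac: float = 2 / 3
    flp_low: float = 0.15
    flp_high: float = 0.6
    base_logit: float = -2.2
    sanction_logodds: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2 or self.n < 2:
            raise ParameterError("need K >= 2 and n >= 2")
        for nm in ("restrictive_frac", "flp_low", "flp_high"):
            _check_prob(nm, getattr(self, nm))


def gen_sanction_study(sc: SanctionScenario) -> SurveyTable:
    """IPV risk rises by ``sanction_logodds`` only for FLP=1 respondents
    living in a restrictive-regime cluster."""
    rng = np.random.default_rng(sc.seed)
    n_restrictive = int(round(sc.K * sc.restrictive_frac))
    regime = np.zeros(sc.K, dtype=int)
    regime[rng.permutation(sc.K)[:n_restrictive]] = 1  # 1 = restrictive
    flp_p = np.where(regime == 1, sc.flp_low, sc.flp_high)
    flp = (rng.random((sc.K, sc.n)) < flp_p[:, None]).astype(int)
    logit = sc.base_logit + sc.sanction_logodds * flp * regime[:, None]
    ipv = (rng.random((sc.K, sc.n)) < expit(logit)).astype(int)
    df = pd.DataFrame({
        "person_id": [f"p{i:06d}" for i in range(sc.K * sc.n)],
        "cluster_id": np.repeat([f"c{j:04d}" for j in range(sc.K)], sc.n),
        "weight": 1.0,
        "flp": flp.ravel(),
        "ipv": ipv.ravel(),
        "truth_regime": np.repeat(
            np.where(regime == 1, "restrictive", "non_restrictive"), sc.n),
    })
    schema = SurveySchema(
        weight="weight",
        items={"flp": Domain("binary")},
        outcomes={"ipv": Domain("binary")},
    )
    return SurveyTable(df, schema, check=False)


# ---------------------------------------------------------------------------
# Case study 3: taboo gap between attitudes and derived behaviour


@dataclasses.dataclass
class TabooScenario:
    """Strata of adults (attitudes + event ages) and adolescents whose
    outcome risk is log-linear in the stratum's realized discordance."""

    S: int = 18
    n_adult: int = 200
    n_adol: int = 300
    disapprove_range: tuple[float, float] = (0.6, 0.95)
    behaviour_range: tuple[float, float] = (0.4, 0.9)
    rr_per_10pts: float = 1.27
    base_risk: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rr_per_10pts <= 0:
            raise ParameterError("rr_per_10pts must be > 0")
        if not 0.0 < self.base_risk < 1.0:
            raise ParameterError("base_risk must be in (0, 1)")
        for nm in ("disapprove_range", "behaviour_range"):
            lo, hi = getattr(self, nm)
            _check_prob(nm, lo)
            _check_prob(nm, hi)
            if lo > hi:
                raise ParameterError(f"{nm} interval reversed")


def gen_taboo_study(sc: TabooScenario) -> SurveyTable:
    """Adults carry the "should wait until marriage" attitude plus ages at
    first sex/marriage constructed so that P(first sex < first marriage)
    equals the stratum behaviour prevalence; adolescents carry an HIV
    indicator with log risk = log(base) + log(rr) * (D_s / 0.10)."""
    rng = np.random.default_rng(sc.seed)
    chunks = []
    for s in range(sc.S):
        sid = f"s{s:03d}"
        d_s = rng.uniform(*sc.disapprove_range)   # P(endorse "should wait")
        b_s = rng.uniform(*sc.behaviour_range)    # P(premarital sex)
        wait = (rng.random(sc.n_adult) < d_s).astype(int)
        marriage_age = rng.uniform(15, 30, sc.n_adult)
        premarital = rng.random(sc.n_adult) < b_s
        sex_age = np.where(
            premarital,
            np.maximum(10.0, marriage_age - rng.exponential(1.0, sc.n_adult)),
            marriage_age + rng.uniform(0, 5, sc.n_adult),
        )
        # realized discordance from the adult sample itself
        behaviour_real = float(np.mean(sex_age < marriage_age))
        approval_real = 1.0 - float(np.mean(wait))
        D_s = behaviour_real - approval_real
        risk = sc.base_risk * sc.rr_per_10pts ** (D_s / 0.10)
        if risk > 1.0:
            raise ParameterError(
                f"configured risk {risk:.3f} > 1 in stratum {sid}; "
                "reduce rr_per_10pts or base_risk")
        hiv = (rng.random(sc.n_adol) < risk).astype(int)
        na, ny = sc.n_adult, sc.n_adol
        chunks.append(pd.DataFrame({
            "person_id": ([f"{sid}a{i:05d}" for i in range(na)]
                          + [f"{sid}y{i:05d}" for i in range(ny)]),
            "cluster_id": sid, "stratum_id": sid,
            "cohort": ["adult"] * na + ["adolescent"] * ny,
            "weight": 1.0,
            "wait_item": np.concatenate([wait.astype(float), np.full(ny, np.nan)]),
            "age_first_sex": np.concatenate([sex_age, np.full(ny, np.nan)]),
            "age_first_marriage": np.concatenate([marriage_age, np.full(ny, np.nan)]),
            "ever_married": np.concatenate([np.ones(na), np.full(ny, np.nan)]),
            "hiv": np.concatenate([np.full(na, np.nan), hiv.astype(float)]),
            "truth_discordance": D_s,
        }))
    df = pd.concat(chunks, ignore_index=True)
    schema = SurveySchema(
        stratum_id="stratum_id", weight="weight",
        items={"wait_item": Domain("binary"), "ever_married": Domain("binary")},
        outcomes={"hiv": Domain("binary")},
    )
    return SurveyTable(df, schema, check=False)


# ---------------------------------------------------------------------------
# Case study 4: sex-differentiated item batteries in school x grade cells


@dataclasses.dataclass
class ExpressionScenario:
    """School x grade cells of students answering an item battery whose
    endorsement differs by sex (log-odds per item in ``item_effects``)."""

    n_schools: int = 10
    grades_per_school: int = 4
    students_per_cell: int = 25
    n_items: int = 26
    item_effects: Sequence[float] | None = None  # default: all 1.0
    norm_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ParameterError("need at least one item")
        if self.students_per_cell < 2:
            raise ParameterError("need >= 2 students per cell")
        if self.item_effects is None:
            self.item_effects = tuple(1.0 for _ in range(self.n_items))
        if len(self.item_effects) != self.n_items:
            raise ParameterError("item_effects length must equal n_items")


def gen_expression_study(sc: ExpressionScenario) -> SurveyTable:
    """Item j is endorsed with probability expit(+e_j/2) by girls and
    expit(-e_j/2) by boys, plus an optional N(0, norm_shift_sd) cell-level
    shift common to all items in the cell."""
    rng = np.random.default_rng(sc.seed)
    eff = np.asarray(sc.item_effects, dtype=float)
    n_cells = sc.n_schools * sc.grades_per_school
    N = n_cells * sc.students_per_cell
    school = np.repeat(np.arange(sc.n_schools), sc.grades_per_school * sc.students_per_cell)
    grade = np.tile(np.repeat(np.arange(sc.grades_per_school), sc.students_per_cell),
                    sc.n_schools)
    cell = school * sc.grades_per_school + grade
    female = rng.random(N) < 0.5
    shift = rng.normal(0.0, sc.norm_shift_sd, n_cells) if sc.norm_shift_sd > 0 else np.zeros(n_cells)
    sgn = np.where(female, 0.5, -0.5)
    logits = sgn[:, None] * eff[None, :] + shift[cell][:, None]
    items = (rng.random((N, sc.n_items)) < expit(logits)).astype(int)
    df = pd.DataFrame({
        "person_id": [f"p{i:06d}" for i in range(N)],
        "cluster_id": [f"sch{s:03d}" for s in school],
        "school": [f"sch{s:03d}" for s in school],
        "grade": [f"g{g:02d}" for g in grade],
        "sex": np.where(female, "F", "M"),
    })
    item_names = [f"item_{j:02d}" for j in range(sc.n_items)]
    for j, nm in enumerate(item_names):
        df[nm] = items[:, j]
    schema = SurveySchema(
        sex="sex", group_keys=("school", "grade"),
        items={nm: Domain("binary") for nm in item_names},
    )
    return SurveyTable(df, schema, check=False)


# ---------------------------------------------------------------------------
# Case study 5: village nomination networks with norm-correlated childbirth


@dataclasses.dataclass
class NetworkScenario:
    """Village census networks: girls and other residents nominate
    within-village contacts through name generators; girls' adolescent
    childbirth is clustered on the network (autologistic contagion)."""

    n_villages: int = 50
    girls_per_village: int = 40
    others_per_village: int = 40
    generator_set: tuple[str, ...] = (
        "family", "friend", "advice", "money", "meals", "health", "partner")
    mean_outdegree: float = 6.0
    reciprocity_prob: float = 0.3
    contagion_logodds: float = 0.9
    base_logit: float = -1.5
    other_childbirth_p: float = 0.3
    village_injunctive_probs: Sequence[float] | None = None
    gibbs_sweeps: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_outdegree < 0:
            raise ParameterError("mean_outdegree must be >= 0")
        if len(self.generator_set) > 14:
            raise ParameterError("at most 14 name generators")
        _check_prob("reciprocity_prob", self.reciprocity_prob)
        _check_prob("other_childbirth_p", self.other_childbirth_p)
        if self.village_injunctive_probs is not None:
            for p in self.village_injunctive_probs:
                _check_prob("village_injunctive_probs", p)


def gen_network_study(sc: NetworkScenario) -> tuple[SurveyTable, NominationTable]:
    """Generate a village census survey plus nominations.

    Childbirth among girls follows an autologistic model on the undirected
    within-village graph: conditional log-odds = base_logit +
    contagion_logodds * (number of network neighbours with childbirth).
    Non-girl residents keep an independent Bernoulli childbirth status and
    act as the fixed field of the Gibbs sampler.
    """
    rng = np.random.default_rng(sc.seed)
    n_gen = len(sc.generator_set)
    vil_inj = (np.asarray(sc.village_injunctive_probs, float)
               if sc.village_injunctive_probs is not None
               else rng.uniform(0.2, 0.8, sc.n_villages))
    if len(vil_inj) != sc.n_villages:
        raise ParameterError("village_injunctive_probs length must equal n_villages")

    survey_rows = []
    nom_rows = []
    for v in range(sc.n_villages):
        vid = f"v{v:03d}"
        n_g, n_o = sc.girls_per_village, sc.others_per_village
        n_all = n_g + n_o
        pids = [f"{vid}_{i:04d}" for i in range(n_all)]
        is_girl = np.zeros(n_all, bool)
        is_girl[:n_g] = True
        sex = np.where(is_girl, "F",
                       np.where(rng.random(n_all) < 0.5, "F", "M"))
        sex[:n_g] = "F"
        age = np.where(is_girl, rng.uniform(15, 20, n_all), rng.uniform(21, 70, n_all))

        # nominations: Poisson out-degree, alters without replacement
        adj = np.zeros((n_all, n_all), bool)  # directed ego -> alter
        strength = {}
        for i in range(n_all):
            d = min(rng.poisson(sc.mean_outdegree), n_all - 1)
            if d == 0:
                continue
            alters = rng.choice(np.delete(np.arange(n_all), i), size=d, replace=False)
            for j in alters:
                k = 1 + rng.binomial(n_gen - 1, 0.15)
                labels = rng.choice(n_gen, size=k, replace=False)
                adj[i, j] = True
                strength[(i, j)] = labels
                if rng.random() < sc.reciprocity_prob and not adj[j, i]:
                    adj[j, i] = True
                    strength[(j, i)] = labels.copy()
        und = adj | adj.T  # undirected neighbourhood for the contagion field

        childbirth = np.zeros(n_all, int)
        childbirth[~is_girl & (sex == "F")] = (
            rng.random(int((~is_girl & (sex == "F")).sum())) < sc.other_childbirth_p
        ).astype(int)
        # Gibbs sweeps over girls; stationary conditional = planted logit
        girls_idx = np.flatnonzero(is_girl)
        childbirth[girls_idx] = (rng.random(n_g) < expit(sc.base_logit)).astype(int)
        for _ in range(sc.gibbs_sweeps):
            for i in girls_idx:
                cnt = int(childbirth[und[i]].sum())
                p = expit(sc.base_logit + sc.contagion_logodds * cnt)
                childbirth[i] = int(rng.random() < p)

        believes_good = (rng.random(n_all) < vil_inj[v]).astype(int)
        inj_answer = np.where(believes_good == 1, "good",
                              np.where(rng.random(n_all) < 0.5, "bad", "neither"))
        for i in range(n_all):
            survey_rows.append((pids[i], vid, vid, 1.0, sex[i], float(age[i]),
                                int(childbirth[i]) if sex[i] == "F" else 0,
                                inj_answer[i], int(is_girl[i])))
        for (i, j), labels in strength.items():
            for lab in labels:
                nom_rows.append((pids[i], pids[j], sc.generator_set[lab], vid))

    survey = pd.DataFrame(survey_rows, columns=[
        "person_id", "cluster_id", "village", "weight", "sex", "age",
        "childbirth", "village_thinks", "truth_is_girl"])
    noms = pd.DataFrame(nom_rows, columns=list(NominationTable.COLUMNS))
    schema = SurveySchema(
        weight="weight", sex="sex", age="age", group_keys=("village",),
        items={"village_thinks": Domain("categorical",
                                        levels=("good", "bad", "neither"))},
        outcomes={"childbirth": Domain("binary")},
    )
    return (SurveyTable(survey, schema, check=False),
            NominationTable(noms, sc.generator_set, check=False))
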