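"""Ego-network norm proxies from village name-generator censuses.

Nominations elicited by up to 14 name generators are collapsed to a
weighted digraph: the tie strength of ego -> alter is the number of
distinct generators through which ego nominated alter, and an unordered
pair's direction is ``out``, ``in`` or ``both`` relative to the focal
ego.  Descriptive-norm proxies for an ego are the any/share/weighted
share of her alters with the behaviour; the injunctive proxy is the
share of alters who themselves believe the village approves.  Village
aggregates (childbirth rate among female participants, approval share
with good vs bad/neither) complete the interpersonal measures, and a
cluster-robust logistic model relates a girl's own childbirth to the
chosen proxies.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import IntegrityError, NominationTable, ParameterError, SurveyTable
from . import estimators
from .estimators import FitResult


class NormNetwork:
    """Directed weighted graph with generator-label sets per edge."""

    def __init__(self, graph: nx.DiGraph, survey: SurveyTable):
        self.graph = graph
        self.survey = survey
        self._attrs = survey.df.set_index(
            survey.df[survey.schema.person_id].astype(str))

    def strength(self, ego: str, alter: str) -> int:
        return len(self.graph[ego][alter]["generators"])

    def direction(self, ego: str, alter: str) -> str:
        out_tie = self.graph.has_edge(ego, alter)
        in_tie = self.graph.has_edge(alter, ego)
        if out_tie and in_tie:
            return "both"
        if out_tie:
            return "out"
        if in_tie:
            return "in"
        raise ParameterError(f"no tie between {ego!r} and {alter!r}")

    def attribute(self, person: str, var: str):
        return self._attrs.loc[person, var]


@dataclasses.dataclass
class EgoNormProxies:
    ego_id: str
    n_alters: int
    any_alter_childbirth: float          # 0/1, NaN when no alters
    share_alters_childbirth: float
    weighted_share: float
    n_alters_childbirth: float           # count, convenience for modelling
    share_alters_believe_village_approves: float
    village_childbirth_rate: float
    village_approval_share: float
    flag: str | None = None


def build_network(noms: NominationTable, survey: SurveyTable) -> NormNetwork:
    """Collapse the nomination multigraph to a digraph with label sets.

    Every ego/alter must appear in the survey; edges must stay within one
    village (checked against the survey's village assignment).
    """
    pid = survey.schema.person_id
    known = set(survey.df[pid].astype(str))
    village_col = (survey.schema.group_keys[0] if survey.schema.group_keys
                   else survey.schema.cluster_id)
    vmap = dict(zip(survey.df[pid].astype(str),
                    survey.df[village_col].astype(str)))
    ids = set(noms.df["ego_id"].astype(str)) | set(noms.df["alter_id"].astype(str))
    missing = sorted(ids - known)
    if missing:
        raise IntegrityError(f"nomination ids absent from survey: {missing[:10]}")
    g = nx.DiGraph()
    for pid_, v in vmap.items():
        g.add_node(pid_, village=v)
    for ego, alter, gen in noms.df[["ego_id", "alter_id", "generator"]].astype(str).itertuples(index=False):
        if vmap[ego] != vmap[alter]:
            raise IntegrityError(f"cross-village tie {ego!r} -> {alter!r}")
        if g.has_edge(ego, alter):
            g[ego][alter]["generators"].add(gen)
        else:
            g.add_edge(ego, alter, generators={gen})
    for u, v, d in g.edges(data=True):
        d["strength"] = len(d["generators"])
    return NormNetwork(g, survey)


def _alters(net: NormNetwork, ego: str, direction_filter: str) -> list[tuple[str, int]]:
    """(alter, strength) pairs under a direction filter.

    Strength of an in-only tie is the strength of the alter's nomination.
    For pairs tied in both directions the ego's own out-strength is used.
    """
    g = net.graph
    out_n = {a: g[ego][a]["strength"] for a in g.successors(ego)}
    in_n = {a: g[a][ego]["strength"] for a in g.predecessors(ego)}
    if direction_filter == "out":
        sel = out_n
    elif direction_filter == "in":
        sel = in_n
    elif direction_filter == "both":
        sel = {a: out_n[a] for a in out_n if a in in_n}
    elif direction_filter == "any":
        sel = {**in_n, **out_n}  # out-strength wins for reciprocated pairs
    else:
        raise ParameterError(f"unknown direction filter {direction_filter!r}")
    return sorted(sel.items())


def village_aggregates(survey: SurveyTable, village_var: str | None = None,
                       childbirth_var: str = "childbirth",
                       injunctive_var: str = "village_thinks") -> pd.DataFrame:
    """Per-village childbirth rate (female participants) and approval share.

    The injunctive item is binarised good vs bad/neither.  A village with
    no female participants gets a missing childbirth rate and a flag.
    """
    sch = survey.schema
    village_var = village_var or (sch.group_keys[0] if sch.group_keys
                                  else sch.cluster_id)
    df = survey.df
    lvl = {"good", "bad", "neither"}
    obs = set(df[injunctive_var].dropna().astype(str))
    if not obs <= lvl:
        raise ParameterError(f"injunctive answers outside {sorted(lvl)}: "
                             f"{sorted(obs - lvl)[:5]}")
    rows = []
    for vid, grp in df.groupby(village_var, sort=True):
        fem = grp[grp[sch.sex] == "F"] if sch.sex else grp
        cb = pd.to_numeric(fem[childbirth_var], errors="coerce").dropna()
        rate = float(cb.mean()) if len(cb) else float("nan")
        inj = grp[injunctive_var].dropna().astype(str)
        approval = float((inj == "good").mean()) if len(inj) else float("nan")
        rows.append({"village": str(vid), "childbirth_rate": rate,
                     "approval_share": approval,
                     "flag": None if len(cb) else "no female participants"})
    return pd.DataFrame(rows)


def ego_proxies(net: NormNetwork, ego: str, behaviour_var: str = "childbirth",
                belief_var: str = "village_thinks",
                direction_filter: str = "any",
                weight_by_strength: bool = False,
                village_table: pd.DataFrame | None = None,
                min_strength: int = 1) -> EgoNormProxies:
    """Interpersonal and village-level norm proxies for one ego.

    Alters with missing behaviour/belief drop out of the respective
    denominator; zero-alter egos get missing proxies with a flag.
    ``min_strength`` keeps only "important" contacts at or above a tie
    strength floor (default 1, i.e. all contacts).
    """
    if ego not in net.graph:
        raise ParameterError(f"unknown ego {ego!r}")
    pairs = [(a, s) for a, s in _alters(net, ego, direction_filter)
             if s >= min_strength]
    vid = net.graph.nodes[ego]["village"]
    if village_table is not None:
        vrow = village_table[village_table["village"] == vid]
        v_rate = float(vrow["childbirth_rate"].iloc[0]) if len(vrow) else float("nan")
        v_appr = float(vrow["approval_share"].iloc[0]) if len(vrow) else float("nan")
    else:
        v_rate = v_appr = float("nan")
    if not pairs:
        return EgoNormProxies(ego, 0, *(float("nan"),) * 5, v_rate, v_appr,
                              flag="no alters under filter")
    beh, beh_w, bel = [], [], []
    for alter, s in pairs:
        b = net.attribute(alter, behaviour_var)
        if pd.notna(b):
            beh.append(float(b))
            beh_w.append(float(s) if weight_by_strength else 1.0)
        ans = net.attribute(alter, belief_var)
        if pd.notna(ans):
            bel.append(1.0 if str(ans) == "good" else 0.0)
    share = float(np.average(beh)) if beh else float("nan")
    wshare = float(np.average(beh, weights=beh_w)) if beh else float("nan")
    count = float(np.sum(beh)) if beh else float("nan")
    return EgoNormProxies(
        ego_id=ego, n_alters=len(pairs),
        any_alter_childbirth=(float(share > 0) if beh else float("nan")),
        share_alters_childbirth=share, weighted_share=wshare,
        n_alters_childbirth=count,
        share_alters_believe_village_approves=(float(np.mean(bel)) if bel
                                               else float("nan")),
        village_childbirth_rate=v_rate, village_approval_share=v_appr)


def all_ego_proxies(net: NormNetwork, egos: Iterable[str] | None = None,
                    **kw) -> pd.DataFrame:
    """ego_proxies over many egos as a DataFrame (column per proxy)."""
    if egos is None:
        egos = sorted(net.graph.nodes)
    villages = village_aggregates(net.survey,
                                  childbirth_var=kw.get("behaviour_var", "childbirth"),
                                  injunctive_var=kw.get("belief_var", "village_thinks"))
    rows = [dataclasses.asdict(ego_proxies(net, e, village_table=villages, **kw))
            for e in egos]
    return pd.DataFrame(rows)


def childbirth_model(girls: SurveyTable, proxies: pd.DataFrame,
                     terms: Sequence[str], covariates: Sequence[str] = (),
                     outcome: str = "childbirth",
                     village_var: str | None = None) -> FitResult:
    """Cluster-robust (by village) logistic fit of a girl's childbirth on
    selected network norm proxies.

    ``proxies`` is the frame from all_ego_proxies; terms name its proxy
    columns; covariates name columns of the girls table.  A constant
    proxy is flagged inestimable.
    """
    sch = girls.schema
    village_var = village_var or (sch.group_keys[0] if sch.group_keys
                                  else sch.cluster_id)
    df = girls.df.merge(proxies.rename(columns={"ego_id": sch.person_id}),
                        on=sch.person_id, how="inner")
    for t in terms:
        if df[t].dropna().nunique() < 2:
            return FitResult({}, {}, {}, len(df), df[village_var].nunique(),
                             False, "logistic",
                             flags=(f"inestimable: proxy {t!r} constant",))
    sub = SurveyTable(df, sch, check=False)
    return estimators.weighted_glm(sub, outcome, [*terms, *covariates],
                                   family="logistic", cluster_var=village_var)


def attenuation(beta_without: float, beta_with: float) -> float:
    """1 - beta_with/beta_without: how much a coefficient shrinks when the
    village aggregate joins an interpersonal-only model."""
    if beta_without == 0:
        return float("nan")
    return 1.0 - beta_with / beta_without
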