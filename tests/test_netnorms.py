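"""Tie strength/direction against brute-force recounts, ego proxy
arithmetic, and village aggregates."""

import numpy as np
import pandas as pd
import pytest

from normproxy import netnorms, synthdata
from normproxy.datamodel import (
    Domain,
    IntegrityError,
    NominationTable,
    SurveySchema,
    SurveyTable,
)
from normproxy.netnorms import (
    all_ego_proxies,
    attenuation,
    build_network,
    ego_proxies,
    village_aggregates,
)

GENS = tuple(f"g{i}" for i in range(5))


def _survey(people, village="v1", **cols):
    df = pd.DataFrame({
        "person_id": people,
        "cluster_id": village,
        "village": village,
        "sex": cols.get("sex", ["F"] * len(people)),
        "childbirth": cols.get("childbirth", [0] * len(people)),
        "village_thinks": cols.get("village_thinks", ["bad"] * len(people)),
    })
    sch = SurveySchema(sex="sex", group_keys=("village",),
                       outcomes={"childbirth": Domain("binary")})
    return SurveyTable(df, sch, check=False)


def _noms(triples, village="v1"):
    df = pd.DataFrame([(e, a, g, village) for e, a, g in triples],
                      columns=["ego_id", "alter_id", "generator", "village_id"])
    return NominationTable(df, GENS, check=False)


class TestBuildNetwork:
    def test_strength_counts_generators(self):
        s = _survey(["e", "a"])
        net = build_network(_noms([("e", "a", "g0"), ("e", "a", "g1"),
                                   ("e", "a", "g2")]), s)
        assert net.strength("e", "a") == 3

    def test_direction_both_requires_reciprocation(self):
        s = _survey(["e", "a", "b"])
        net = build_network(_noms([("e", "a", "g0"), ("a", "e", "g1"),
                                   ("e", "b", "g0")]), s)
        assert net.direction("e", "a") == "both"
        assert net.direction("e", "b") == "out"
        assert net.direction("b", "e") == "in"

    def test_unknown_id_rejected(self):
        s = _survey(["e"])
        with pytest.raises(IntegrityError, match="ghost"):
            build_network(_noms([("e", "ghost", "g0")]), s)

    def test_brute_force_recount_on_random_tables(self, rng):
        for trial in range(30):
            people = [f"p{i}" for i in range(8)]
            triples = set()
            for _ in range(rng.integers(5, 25)):
                e, a = rng.choice(people, 2, replace=False)
                triples.add((e, a, GENS[rng.integers(0, len(GENS))]))
            s = _survey(people)
            net = build_network(_noms(sorted(triples)), s)
            # brute-force per-pair recount
            count = {}
            for e, a, g in triples:
                count.setdefault((e, a), set()).add(g)
            for (e, a), gens in count.items():
                assert net.strength(e, a) == len(gens)
                want = "both" if (a, e) in count else "out"
                assert net.direction(e, a) == want


class TestEgoProxies:
    def test_share_and_any(self):
        s = _survey(["e", "a1", "a2", "a3"], childbirth=[0, 1, 0, 0])
        net = build_network(_noms([("e", "a1", "g0"), ("e", "a2", "g0"),
                                   ("e", "a3", "g0")]), s)
        p = ego_proxies(net, "e", direction_filter="out")
        assert p.share_alters_childbirth == pytest.approx(1 / 3)
        assert p.any_alter_childbirth == 1.0
        assert p.n_alters_childbirth == 1.0

    def test_strength_weighted_share(self):
        s = _survey(["e", "a1", "a2", "a3"], childbirth=[0, 1, 0, 0])
        triples = ([("e", "a1", g) for g in GENS]           # strength 5
                   + [("e", "a2", "g0"), ("e", "a3", "g0")])  # strength 1 each
        net = build_network(_noms(triples), s)
        p = ego_proxies(net, "e", direction_filter="out", weight_by_strength=True)
        assert p.weighted_share == pytest.approx(5 / 7)

    def test_equal_strengths_collapse_to_share(self, rng):
        sc = synthdata.NetworkScenario(n_villages=2, girls_per_village=10,
                                       others_per_village=10, seed=71)
        survey, noms = synthdata.gen_network_study(sc)
        df = noms.df.drop_duplicates(["ego_id", "alter_id"]).copy()
        df["generator"] = sc.generator_set[0]  # force strength 1 everywhere
        net = build_network(NominationTable(df, sc.generator_set, check=False),
                            survey)
        for ego in list(net.graph.nodes)[:10]:
            p = ego_proxies(net, ego, direction_filter="any",
                            weight_by_strength=True)
            if p.n_alters and not np.isnan(p.share_alters_childbirth):
                assert p.weighted_share == pytest.approx(p.share_alters_childbirth)

    def test_zero_alter_ego_flagged(self):
        s = _survey(["e", "a"])
        net = build_network(_noms([("a", "e", "g0")]), s)
        p = ego_proxies(net, "e", direction_filter="out")
        assert p.n_alters == 0
        assert np.isnan(p.share_alters_childbirth)
        assert p.flag == "no alters under filter"

    def test_injunctive_share_uses_alters_own_answers(self):
        s = _survey(["e", "a1", "a2"],
                    village_thinks=["bad", "good", "neither"])
        net = build_network(_noms([("e", "a1", "g0"), ("e", "a2", "g0")]), s)
        p = ego_proxies(net, "e", direction_filter="out")
        assert p.share_alters_believe_village_approves == pytest.approx(0.5)


class TestVillageAggregates:
    def test_childbirth_rate_over_females(self):
        s = _survey(["a", "b", "c", "d", "e"],
                    sex=["F", "F", "F", "F", "M"],
                    childbirth=[1, 0, 0, 0, 0])
        va = village_aggregates(s)
        assert va["childbirth_rate"].iloc[0] == pytest.approx(0.25)

    def test_good_vs_bad_neither_binarisation(self):
        s = _survey(["a", "b", "c", "d"],
                    village_thinks=["good", "bad", "neither", "good"])
        va = village_aggregates(s)
        assert va["approval_share"].iloc[0] == pytest.approx(0.5)

    def test_brute_force_group_by(self, rng):
        frames = []
        for v in range(20):
            n = int(rng.integers(3, 10))
            frames.append(pd.DataFrame({
                "person_id": [f"v{v}p{i}" for i in range(n)],
                "cluster_id": f"v{v}", "village": f"v{v}",
                "sex": rng.choice(["F", "M"], n),
                "childbirth": rng.integers(0, 2, n),
                "village_thinks": rng.choice(["good", "bad", "neither"], n),
            }))
        df = pd.concat(frames, ignore_index=True)
        sch = SurveySchema(sex="sex", group_keys=("village",))
        va = village_aggregates(SurveyTable(df, sch, check=False))
        for _, row in va.iterrows():
            sub = df[df["village"] == row["village"]]
            fem = sub[sub["sex"] == "F"]
            if len(fem):
                assert row["childbirth_rate"] == pytest.approx(
                    fem["childbirth"].mean(), abs=1e-12)
            assert row["approval_share"] == pytest.approx(
                (sub["village_thinks"] == "good").mean(), abs=1e-12)

    def test_row_order_invariance(self, rng):
        s = _survey([f"p{i}" for i in range(10)],
                    childbirth=list(rng.integers(0, 2, 10)))
        shuffled = SurveyTable(s.df.sample(frac=1, random_state=0), s.schema,
                               check=False)
        pd.testing.assert_frame_equal(village_aggregates(s),
                                      village_aggregates(shuffled))


class TestChildbirthModel:
    def test_constant_proxy_inestimable(self):
        sc = synthdata.NetworkScenario(n_villages=3, girls_per_village=10,
                                       others_per_village=10, seed=72)
        survey, noms = synthdata.gen_network_study(sc)
        net = build_network(noms, survey)
        girls = survey.df[survey.df["truth_is_girl"] == 1]
        gt = SurveyTable(girls, survey.schema, check=False)
        prox = all_ego_proxies(net, egos=sorted(girls["person_id"]))
        prox["share_alters_childbirth"] = 0.5
        fit = netnorms.childbirth_model(gt, prox, ["share_alters_childbirth"])
        assert not fit.converged

    def test_attenuation_formula(self):
        assert attenuation(0.8, 0.6) == pytest.approx(0.25)
        assert np.isnan(attenuation(0.0, 0.5))

    def test_orthogonal_village_aggregate_no_attenuation(self):
        sc = synthdata.NetworkScenario(n_villages=20, girls_per_village=25,
                                       others_per_village=25,
                                       contagion_logodds=0.9, seed=73)
        survey, noms = synthdata.gen_network_study(sc)
        net = build_network(noms, survey)
        girls = survey.df[survey.df["truth_is_girl"] == 1]
        gt = SurveyTable(girls, survey.schema, check=False)
        prox = all_ego_proxies(net, egos=sorted(girls["person_id"]),
                               direction_filter="any")
        # replace the village aggregate with independent noise
        rng = np.random.default_rng(0)
        prox["village_childbirth_rate"] = rng.random(len(prox))
        f1 = netnorms.childbirth_model(gt, prox, ["n_alters_childbirth"])
        f2 = netnorms.childbirth_model(
            gt, prox, ["n_alters_childbirth", "village_childbirth_rate"])
        att = attenuation(f1.coefficients["n_alters_childbirth"],
                          f2.coefficients["n_alters_childbirth"])
        assert abs(att) < 0.15
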