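"""Term-level similarity: the unified engine, the registry, corrections."""

import itertools
import math

import pytest

from gosim import (
    MeasureContext,
    OntologyError,
    SimilarityParams,
    disjunctive_common_ancestors,
    epsilon,
    informative_common_ancestors,
    list_measures,
    measure,
    mica,
    mu,
    unified_similarity,
    wang_svalues,
)
from gosim.fixtures import HELICASE_TERMS, DagSpec, random_corpus, random_dag
from gosim.similarity import INF, REGISTRY

from conftest import LN2, LN3, LN4, LN32

LIN_CD = 2 * LN32 / (LN32 + LN3)  # lin(c, d) on the diamond corpus


class TestMu:
    def test_max_functional_recovers_ic(self, uni_ctx, diamond_graph):
        assert mu(diamond_graph.ancestors("d"), uni_ctx.ic.ic, INF) == pytest.approx(
            LN4, abs=1e-12
        )
        assert mu({"r"}, uni_ctx.ic.ic, INF) == 0.0

    def test_sum_functional_recovers_semantic_value(self, diamond_graph):
        prof = wang_svalues(diamond_graph, "d")
        assert mu(diamond_graph.ancestors("d"), prof.svalues, 1) == pytest.approx(
            3.592, abs=1e-12
        )

    def test_empty_set_is_an_error(self, uni_ctx):
        with pytest.raises(OntologyError, match="empty"):
            mu(set(), uni_ctx.ic.ic, INF)

    def test_undefined_specificity_propagates(self):
        assert math.isnan(mu({"x"}, {"x": math.nan}, 1))


class TestMica:
    def test_tie_broken_to_smallest_id(self, ann_ctx):
        # common ancestors of (c, d) are {c, a, b, r}; b and c tie at ln(3/2)
        term, value = mica(ann_ctx, "c", "d")
        assert term == "b"
        assert value == pytest.approx(LN32, abs=1e-12)

    def test_self_pair(self, ann_ctx):
        assert mica(ann_ctx, "d", "d") == ("d", pytest.approx(LN3, abs=1e-12))

    def test_siblings_share_only_the_root(self, uni_ctx):
        term, value = mica(uni_ctx, "a", "b")
        assert term == "r" and value == 0.0

    def test_cross_namespace_pair_rejected(self, diamond_graph):
        from gosim import Edge, OntologyGraph, Term

        terms = list(diamond_graph.terms.values()) + [Term("q", namespace="other")]
        g2 = OntologyGraph(terms, list(diamond_graph.edges()))
        ctx = MeasureContext(g2, "universal")
        with pytest.raises(OntologyError, match="different namespaces"):
            mica(ctx, "a", "q")


class TestAncestorLists:
    def test_informative_ancestors_annotation(self, ann_ctx):
        ica = informative_common_ancestors(ann_ctx, "c", "d")
        assert set(ica) == {"b", "c"}
        assert ica[-1] == "b"  # the MICA comes last

    def test_informative_ancestors_universal(self, uni_ctx):
        ica = informative_common_ancestors(uni_ctx, "c", "d")
        assert set(ica) == {"a", "b", "c"}
        assert ica[-1] == "c"

    def test_root_only_commonality_is_empty(self, uni_ctx):
        assert informative_common_ancestors(uni_ctx, "a", "b") == ()
        assert epsilon(uni_ctx, "xgrasm", "a", "b") == 1.0
        assert measure("xgrasm_lin", "a", "b", uni_ctx) == 0.0

    def test_single_informative_ancestor_gives_mica_only(self, uni_ctx):
        assert disjunctive_common_ancestors(uni_ctx, "a", "c") == ("a",)

    def test_two_disjunctive_ancestors_in_helicase_scenario(self, helicase_graph):
        ctx = MeasureContext(helicase_graph, "universal")
        T = HELICASE_TERMS
        dca = disjunctive_common_ancestors(ctx, T["atp_helicase"], T["dna_helicase"])
        assert dca == (T["ntpase"], T["helicase"])
        # catalytic activity is informative but reaches the pair only through
        # the helicase branch, so it is not disjunctive from the MICA
        ica = informative_common_ancestors(ctx, T["atp_helicase"], T["dna_helicase"])
        assert T["catalytic"] in ica

    def test_mica_only_when_no_independent_path(self, helicase_graph):
        ctx = MeasureContext(helicase_graph, "universal")
        T = HELICASE_TERMS
        dca = disjunctive_common_ancestors(ctx, T["purine_helicase"], T["dna_helicase"])
        assert dca == (T["helicase"],)


class TestEpsilon:
    def test_relevance_closed_form(self, ann_ctx):
        assert epsilon(ann_ctx, "relevance", "c", "d") == pytest.approx(1 / 3, abs=1e-12)

    def test_li_closed_form(self, ann_ctx):
        expected = LN32 / (1 + LN32)
        assert epsilon(ann_ctx, "li", "c", "d") == pytest.approx(expected, abs=1e-12)

    def test_xgrasm_equal_ic_ancestors(self, ann_ctx):
        assert epsilon(ann_ctx, "xgrasm", "c", "d") == pytest.approx(1.0, abs=1e-12)

    def test_zero_mica_ic_defaults_to_one(self, uni_ctx):
        assert epsilon(uni_ctx, "relevance", "a", "b") == 1.0

    def test_helicase_correction_factors(self, helicase_graph):
        ctx = MeasureContext(helicase_graph, "universal")
        T = HELICASE_TERMS
        a, b = T["atp_helicase"], T["dna_helicase"]
        # DCA ICs are ln2 (NTPase) and ln4 (helicase, the MICA)
        assert epsilon(ctx, "grasm", a, b) == pytest.approx(0.75, abs=1e-12)
        # ICA adds catalytic activity (ln2)
        assert epsilon(ctx, "xgrasm", a, b) == pytest.approx(2 / 3, abs=1e-12)

    def test_unknown_rule(self, ann_ctx):
        with pytest.raises(OntologyError, match="unknown epsilon rule"):
            epsilon(ann_ctx, "bogus", "c", "d")


class TestUnifiedEngine:
    def test_lin_parameters(self, ann_ctx):
        params = SimilarityParams(INF, 0, 0.5, 0.5, "one")
        assert unified_similarity(ann_ctx, "c", "d", params) == pytest.approx(
            LIN_CD, abs=1e-12
        )

    def test_identity_for_informative_term(self, ann_ctx):
        params = SimilarityParams(INF, 0, 0.5, 0.5, "one")
        assert unified_similarity(ann_ctx, "d", "d", params) == pytest.approx(1.0)

    def test_max_selected_denominator(self, uni_ctx):
        params = SimilarityParams(INF, 0, 1, 0, "one", select_max=True)
        # IC(c) = IC(d) = ln4 and their MICA is c itself
        assert unified_similarity(uni_ctx, "c", "d", params) == pytest.approx(1.0)

    def test_root_pair_is_zero_by_convention(self, uni_ctx):
        params = SimilarityParams(INF, 0, 0.5, 0.5, "one")
        assert unified_similarity(uni_ctx, "r", "r", params) == 0.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimilarityParams(2, 0, 0.5, 0.5)
        with pytest.raises(ValueError):
            SimilarityParams(INF, 0, 0.1, 0.1)
        with pytest.raises(ValueError):
            SimilarityParams(INF, -1, 1, 1)


class TestRegistryClosedForms:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("resnik_raw", LN32),
            ("resnik_nunivers", LN32 / LN3),
            ("resnik_nunif", LN32 / math.log2(3)),
            ("resnik_nmax", LN32 / LN3),  # ic_max on the diamond corpus is ln3
            ("lin", LIN_CD),
            ("relevance", (1 / 3) * LIN_CD),
            ("li", (LN32 / (1 + LN32)) * LIN_CD),
            ("jc_distance", LN32 + LN3 - 2 * LN32),
            ("jc_couto", 1 / (1 + LN2)),
            ("jc_canonical", LIN_CD),
            ("xgrasm_lin", LIN_CD),  # both informative ancestors tie at ln(3/2)
        ],
    )
    def test_annotation_family_on_diamond(self, ann_ctx, name, expected):
        assert measure(name, "c", "d", ann_ctx) == pytest.approx(expected, abs=1e-12)

    def test_topology_measures_on_diamond(self, uni_ctx, zhang_ctx, wang_ctx):
        assert measure("universal", "c", "d", uni_ctx) == pytest.approx(1.0)
        assert measure("zhang", "c", "d", zhang_ctx) == pytest.approx(1.0)
        assert measure("wang", "c", "d", wang_ctx) == pytest.approx(
            5.832 / (3.24 + 3.592), abs=1e-12
        )

    def test_depth_measures_on_diamond(self, uni_ctx):
        assert measure("wu_palmer", "c", "d", uni_ctx) == pytest.approx(4 / 9, abs=1e-12)
        assert measure("edge_based", "c", "d", uni_ctx) == pytest.approx(2 / 3, abs=1e-12)

    def test_jc_distance_self_pair_is_zero(self, ann_ctx):
        assert measure("jc_distance", "d", "d", ann_ctx) == 0.0

    def test_incompatible_measure_and_model(self, ann_ctx, uni_ctx):
        with pytest.raises(OntologyError, match="incompatible"):
            measure("wang", "c", "d", ann_ctx)
        with pytest.raises(OntologyError, match="incompatible"):
            measure("zhang", "c", "d", uni_ctx)

    def test_unknown_measure(self, ann_ctx):
        with pytest.raises(OntologyError, match="unknown measure"):
            measure("resnik", "c", "d", ann_ctx)

    def test_corpus_scaled_measures_need_annotation_model(self, diamond_graph):
        uni = MeasureContext(diamond_graph, "universal")
        with pytest.raises(OntologyError, match="incompatible"):
            measure("resnik_nunif", "c", "d", uni)

    def test_undefined_ic_propagates_as_nan(self, diamond):
        from gosim import Edge, OntologyGraph, Term

        graph, corpus = diamond
        terms = list(graph.terms.values()) + [Term("orphan", namespace="toy")]
        g2 = OntologyGraph(terms, list(graph.edges()) + [Edge("a", "orphan")])
        ctx = MeasureContext(g2, "annotation", corpus)
        for name in ("lin", "resnik_raw", "jc_couto", "grasm_lin"):
            assert math.isnan(measure(name, "orphan", "d", ctx))


class TestEngineEquivalence:
    """The parameterized engine and each measure's closed form agree."""

    @pytest.mark.parametrize("seed", range(3))
    def test_all_registered_engine_rows(self, seed):
        g = random_dag(DagSpec(n_terms=25, seed=seed))
        corpus = random_corpus(g, n_proteins=12, seed=seed)
        contexts = {
            "annotation": MeasureContext(g, "annotation", corpus),
            "zhang": MeasureContext(g, "zhang"),
            "universal": MeasureContext(g, "universal"),
            "wang": MeasureContext(g, "wang"),
        }
        ids = sorted(g.terms)
        pairs = list(itertools.combinations(ids, 2))[:150]
        for name, mdef in REGISTRY.items():
            if mdef.engine_params is None:
                continue
            model = mdef.ic_models[0] if mdef.ic_models else "universal"
            if mdef.canonical_ic:
                model = mdef.canonical_ic
            ctx = contexts[model]
            for a, b in pairs:
                direct = measure(name, a, b, ctx)
                engine = unified_similarity(ctx, a, b, mdef.engine_params)
                if math.isnan(direct):
                    assert math.isnan(engine)
                else:
                    assert engine == pytest.approx(direct, abs=1e-12), (name, a, b)


class TestMeasureProperties:
    @pytest.mark.parametrize("seed", range(3))
    def test_symmetry_and_range(self, seed):
        g = random_dag(DagSpec(n_terms=25, seed=seed))
        corpus = random_corpus(g, n_proteins=12, seed=seed)
        ctx = MeasureContext(g, "annotation", corpus)
        ids = sorted(g.terms)
        pairs = list(itertools.combinations(ids, 2))[::5][:60]
        for name in ("lin", "relevance", "li", "grasm_lin", "xgrasm_lin",
                     "resnik_nunivers", "jc_couto"):
            for a, b in pairs:
                s_ab = measure(name, a, b, ctx)
                s_ba = measure(name, b, a, ctx)
                if math.isnan(s_ab):
                    assert math.isnan(s_ba)
                    continue
                assert s_ab == pytest.approx(s_ba, abs=1e-12)
                assert -1e-12 <= s_ab <= 1 + 1e-12

    def test_lin_equals_canonical_jc_normalization(self, small_random_dags):
        for g, corpus in small_random_dags[:4]:
            for model in ("annotation", "zhang", "universal"):
                ctx = MeasureContext(g, model, corpus)
                ids = sorted(g.terms)
                for a, b in itertools.combinations(ids, 2):
                    lin = measure("lin", a, b, ctx)
                    jc = measure("jc_canonical", a, b, ctx)
                    if math.isnan(lin):
                        assert math.isnan(jc)
                    else:
                        assert lin == pytest.approx(jc, abs=1e-12)

    def test_resnik_constant_but_nunivers_decreasing_down_chain(self, chain_graph):
        """The raw Resnik score cannot separate a term from increasingly
        specific cousins; the Nunivers normalization restores the expected
        strict decrease."""
        ctx = MeasureContext(chain_graph, "universal")
        chain = ["n3", "n4", "n5", "n6"]
        raws = [measure("resnik_raw", "n2", t, ctx) for t in chain]
        assert all(r == pytest.approx(raws[0], abs=1e-12) for r in raws)
        norm = [measure("resnik_nunivers", "n2", t, ctx) for t in chain]
        for earlier, later in zip(norm, norm[1:]):
            assert later < earlier - 1e-12

    def test_nunivers_non_increasing_in_descendant_specificity(self, uni_ctx):
        # walking a term's partner down a chain can only reduce similarity
        s_cd = measure("resnik_nunivers", "a", "c", uni_ctx)
        s_cd2 = measure("resnik_nunivers", "a", "d", uni_ctx)
        assert s_cd2 <= s_cd + 1e-12

    def test_grasm_equals_xgrasm_when_icas_pairwise_disjunctive(self, small_random_dags):
        checked = 0
        from gosim.similarity import _pairwise_disjunctive

        for g, corpus in small_random_dags[:4]:
            ctx = MeasureContext(g, "annotation", corpus)
            ids = sorted(g.terms)
            for a, b in itertools.combinations(ids, 2):
                ica = informative_common_ancestors(ctx, a, b)
                if len(ica) < 2:
                    continue
                if all(
                    _pairwise_disjunctive(g, u, v, a, b)
                    for u, v in itertools.combinations(ica, 2)
                ):
                    ga = measure("grasm_lin", a, b, ctx)
                    xa = measure("xgrasm_lin", a, b, ctx)
                    if math.isnan(ga):
                        assert math.isnan(xa)
                        continue
                    assert ga == pytest.approx(xa, abs=1e-12)
                    checked += 1
        assert checked > 0

    def test_measure_registry_is_complete(self):
        names = set(list_measures())
        for expected in (
            "resnik_raw", "resnik_nmax", "resnik_nunif", "resnik_nunivers",
            "lin", "relevance", "li", "zhang", "universal", "wang",
            "grasm_lin", "grasm_nmax", "grasm_nunif", "grasm_nunivers",
            "xgrasm_lin", "xgrasm_nmax", "xgrasm_nunif", "xgrasm_nunivers",
            "jc_distance", "jc_couto", "jc_t0", "jc_pesquita", "jc_canonical",
            "wu_palmer", "edge_based",
        ):
            assert expected in names
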