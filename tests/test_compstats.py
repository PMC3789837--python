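"""Exact tests, multiplicity, phenotype/expression/interaction statistics."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metazoanome.compstats import (
    DEFAULT_CLASS_MAP,
    AnnotationBundle,
    PhenotypeClassMap,
    bh_adjust,
    classify_expression,
    classify_phenotypes,
    compare_proportions,
    compare_sets_fisher,
    disease_filter,
    enrich_categories,
    expression_summary,
    fisher_exact_2x2,
    flag_uncharacterized,
    hypergeom_tail,
    interaction_partition,
    read_annotation_bundle,
    write_annotation_bundle,
)


# ---------------------------------------------------------------------------
# enumeration oracles (independent of scipy/statsmodels)


def hypergeom_pmf_exact(N, K, n):
    """Exact pmf over the support, as Fractions."""
    lo, hi = max(0, n - (N - K)), min(n, K)
    denom = comb(N, n)
    return {k: Fraction(comb(K, k) * comb(N - K, n - k), denom) for k in range(lo, hi + 1)}


def fisher_two_sided_oracle(a, b, c, d):
    """Probability-mass rule by direct enumeration with fixed margins."""
    N, r, cM = a + b + c + d, a + b, a + c
    pmf = {
        x: comb(r, x) * comb(N - r, cM - x) / comb(N, cM)
        for x in range(max(0, r + cM - N), min(r, cM) + 1)
    }
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def bh_step_up_oracle(pvals):
    """min over j >= i (by sorted rank) of m * p_(j) / j, capped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = running
    return q


# ---------------------------------------------------------------------------
# hypergeometric


class TestHypergeom:
    def test_forced_enrichment_example(self):
        # draw 4 of 10, 5 marked, all 4 marked: 5 favourable draws of C(10,4)=210
        assert hypergeom_tail(4, 4, 5, 10, "over") == pytest.approx(5 / 210)

    def test_exhaustive_draw_is_certain(self):
        assert hypergeom_tail(5, 10, 5, 10, "over") == pytest.approx(1.0)

    def test_under_at_zero_equals_point_mass(self):
        pmf = hypergeom_pmf_exact(12, 5, 4)
        assert hypergeom_tail(0, 4, 5, 12, "under") == pytest.approx(float(pmf[0]))

    def test_matches_enumeration_on_all_small_parameters(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    pmf = hypergeom_pmf_exact(N, K, n)
                    for k in pmf:
                        over = float(sum(p for x, p in pmf.items() if x >= k))
                        under = float(sum(p for x, p in pmf.items() if x <= k))
                        assert hypergeom_tail(k, n, K, N, "over") == pytest.approx(over, abs=1e-12)
                        assert hypergeom_tail(k, n, K, N, "under") == pytest.approx(under, abs=1e-12)

    @given(
        st.integers(1, 40).flatmap(
            lambda N: st.tuples(
                st.just(N), st.integers(0, N), st.integers(0, N)
            )
        )
    )
    def test_tail_identity(self, params):
        N, K, n = params
        pmf = hypergeom_pmf_exact(N, K, n)
        for k in pmf:
            total = (
                hypergeom_tail(k, n, K, N, "over")
                + hypergeom_tail(k, n, K, N, "under")
                - float(pmf[k])
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_invalid_parameters_are_hard_errors(self):
        with pytest.raises(ValueError):
            hypergeom_tail(5, 4, 5, 10, "over")  # k > n
        with pytest.raises(ValueError):
            hypergeom_tail(2, 4, 1, 10, "over")  # k > K
        with pytest.raises(ValueError):
            hypergeom_tail(1, 4, 5, 10, "sideways")


# ---------------------------------------------------------------------------
# BH adjustment


class TestBH:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_matches_oracle_and_caps_at_one(self, pvals):
        q = bh_adjust(pvals)
        assert q == pytest.approx(bh_step_up_oracle(pvals), abs=1e-12)
        assert all(0 <= x <= 1 for x in q)
        assert all(qi >= pi for qi, pi in zip(q, pvals))

    def test_monotone_on_sorted_input(self):
        q = bh_adjust([0.001, 0.01, 0.02, 0.5, 0.9])
        assert q == sorted(q)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# Fisher exact


class TestFisher:
    def test_diagonal_table(self):
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_symmetric_table_is_one(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)

    def test_balanced_crossover_matches_oracle(self):
        assert fisher_exact_2x2(2, 3, 3, 2) == pytest.approx(fisher_two_sided_oracle(2, 3, 3, 2))

    def test_matches_enumeration_on_moderate_tables(self):
        for N in range(1, 21):
            for r in range(N + 1):
                for c in range(N + 1):
                    for a in range(max(0, r + c - N), min(r, c) + 1):
                        table = (a, r - a, c - a, N - r - c + a)
                        assert fisher_exact_2x2(*table) == pytest.approx(
                            fisher_two_sided_oracle(*table), abs=1e-10
                        )

    def test_label_swap_symmetry(self):
        assert fisher_exact_2x2(7, 3, 2, 8) == pytest.approx(fisher_exact_2x2(2, 8, 7, 3))

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 1, 1, 1)


# ---------------------------------------------------------------------------
# enrichment


def _category_bundle(categories):
    return AnnotationBundle(
        categories=categories,
        phenotypes={},
        has_rnai_data=frozenset(),
        expression_text={},
        interactions=frozenset(),
        omim_map_key={},
        characterized_flags={},
    )


class TestEnrichment:
    def test_direction_over_when_foreground_concentrated(self):
        cats = {f"g{i}": frozenset({"inA" if i < 10 else "inB"}) for i in range(20)}
        bundle = _category_bundle(cats)
        rows = enrich_categories({f"g{i}" for i in range(5)}, set(cats), bundle)
        row = next(r for r in rows if r.category == "inA")
        assert row.direction == "over" and row.p_over < row.p_under
        assert row.k == 5 and row.n == 5 and row.K == 10 and row.N == 20

    def test_planted_fivefold_enrichment_ranks_first(self):
        rng = np.random.default_rng(11)
        cats = [f"c{i}" for i in range(10)]
        weights = np.ones(10)
        background = {f"g{i}": frozenset({cats[rng.integers(0, 10)]}) for i in range(400)}
        w = weights.copy()
        w[0] = 5.0
        w /= w.sum()
        fg = {}
        for i in range(60):
            fg[f"f{i}"] = frozenset({cats[rng.choice(10, p=w)]})
        bundle = _category_bundle({**background, **fg})
        rows = enrich_categories(set(fg), set(background) | set(fg), bundle)
        assert rows[0].category == "c0" and rows[0].direction == "over" and rows[0].significant

    def test_unannotated_genes_excluded_from_denominators(self):
        cats = {"g1": frozenset({"A"}), "g2": frozenset({"A"}), "g3": frozenset()}
        rows = enrich_categories({"g1", "g3"}, {"g1", "g2", "g3"}, _category_bundle(cats))
        (row,) = rows
        assert (row.n, row.N) == (1, 2)

    def test_foreground_outside_background_rejected(self):
        bundle = _category_bundle({"g1": frozenset({"A"})})
        with pytest.raises(ValueError):
            enrich_categories({"gX"}, {"g1"}, bundle)

    def test_unannotated_foreground_rejected(self):
        bundle = _category_bundle({"g1": frozenset({"A"}), "g2": frozenset()})
        with pytest.raises(ValueError):
            enrich_categories({"g2"}, {"g1", "g2"}, bundle)


# ---------------------------------------------------------------------------
# phenotype classes


def _pheno_bundle(phenotypes, rnai=None):
    return AnnotationBundle(
        categories={},
        phenotypes=phenotypes,
        has_rnai_data=frozenset(rnai if rnai is not None else phenotypes),
        expression_text={},
        interactions=frozenset(),
        omim_map_key={},
        characterized_flags={},
    )


class TestPhenotypes:
    def test_class_map_codes_are_disjoint(self):
        with pytest.raises(ValueError):
            PhenotypeClassMap(essential=frozenset({"Emb"}), development=frozenset({"Emb"}))

    def test_single_code_assigns_single_class(self):
        summary = classify_phenotypes(_pheno_bundle({"g": frozenset({"Emb"})}), {"g"})
        assert summary.per_gene_classes["g"] == {"essential"}

    def test_multi_class_membership_allowed(self):
        summary = classify_phenotypes(_pheno_bundle({"g": frozenset({"Gro", "Unc"})}), {"g"})
        assert summary.per_gene_classes["g"] == {"development", "movement"}

    def test_codeless_gene_counts_in_any_denominator_only(self):
        bundle = _pheno_bundle({"g1": frozenset({"Emb"})}, rnai={"g1", "g2"})
        summary = classify_phenotypes(bundle, {"g1", "g2"})
        assert summary.n_rnai == 2 and summary.n_any_phenotype == 1
        assert summary.proportion_any == pytest.approx(0.5)
        assert summary.class_proportions["essential"] == pytest.approx(1.0)

    def test_unknown_code_warns_and_is_ignored(self, caplog):
        bundle = _pheno_bundle({"g": frozenset({"Xyz"})})
        with caplog.at_level("WARNING"):
            summary = classify_phenotypes(bundle, {"g"})
        assert "Xyz" in caplog.text
        assert summary.per_gene_classes["g"] == frozenset()
        assert summary.n_any_phenotype == 1  # still displays a phenotype

    def test_identical_proportions_give_p_one(self):
        a = classify_phenotypes(_pheno_bundle({f"a{i}": frozenset({"Emb"}) for i in range(4)}
                                              | {f"an{i}": frozenset({"Gro"}) for i in range(4)}),
                                [f"a{i}" for i in range(4)] + [f"an{i}" for i in range(4)])
        pvals = compare_sets_fisher(a, a)
        assert all(p == pytest.approx(1.0) for p in pvals.values())

    def test_compare_is_symmetric_under_label_swap(self):
        assert compare_proportions(10, 50, 30, 60) == pytest.approx(
            compare_proportions(30, 60, 10, 50)
        )


# ---------------------------------------------------------------------------
# expression keywords


class TestExpression:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("pan-neuronal expression", {"neuronal"}),
            ("body wall muscle and gonad", {"muscle", "reproductive"}),
            ("germline", {"reproductive"}),
            ("pharyngeal cells", set()),
            ("", set()),
            ("GUT granules; EPIDERMal cells", {"intestinal", "hypodermal"}),
            ("excretory canal and gland cells", {"secretory_excretory"}),
            ("ventral nerve cord; vulval myoblasts", {"neuronal", "muscle"}),
            ("uterine and oocyte expression; spermatheca", {"reproductive"}),
        ],
    )
    def test_keyword_scheme(self, text, expected):
        flags = classify_expression(text)
        assert {t for t, on in flags.as_dict().items() if on} == expected

    def test_idempotent_and_case_insensitive(self):
        assert classify_expression("NEURON") == classify_expression("neuron")

    def test_specific_vs_any_counting(self):
        bundle = AnnotationBundle(
            categories={},
            phenotypes={},
            has_rnai_data=frozenset(),
            expression_text={
                "g1": "head neurons",
                "g2": "head neurons and body wall muscle",
                "g3": "   ",
            },
            interactions=frozenset(),
            omim_map_key={},
            characterized_flags={},
        )
        summary = expression_summary(bundle, {"g1", "g2", "g3"})
        assert summary.n_annotated == 2
        assert summary.any_counts["neuronal"] == 2
        assert summary.any_counts["muscle"] == 1
        assert summary.specific_counts["neuronal"] == 1
        assert summary.specific_counts["muscle"] == 0


# ---------------------------------------------------------------------------
# interactions, disease, characterization


def _edge_bundle(edges):
    return AnnotationBundle(
        categories={},
        phenotypes={},
        has_rnai_data=frozenset(),
        expression_text={},
        interactions=frozenset(frozenset(e) for e in edges),
        omim_map_key={},
        characterized_flags={},
    )


class TestInteractions:
    def test_hand_counted_partition(self):
        part = interaction_partition(_edge_bundle([("a1", "a2"), ("a1", "b1")]), {"a1", "a2"}, {"b1"})
        assert (part.within_a, part.within_b, part.cross) == (1, 0, 1)
        assert part.connected_fraction_a == pytest.approx(1.0)
        assert part.connected_fraction_b == pytest.approx(1.0)
        assert part.n_retained == 2

    def test_no_edges(self):
        part = interaction_partition(_edge_bundle([]), {"a"}, {"b"})
        assert part.n_retained == 0 and part.connected_fraction_a == 0.0
        assert part.pooled_proportions() == {"withinA": 0.0, "withinB": 0.0, "cross": 0.0}

    def test_all_cross(self):
        part = interaction_partition(_edge_bundle([("a1", "b1"), ("a2", "b1")]), {"a1", "a2"}, {"b1"})
        assert part.pooled_proportions() == {"withinA": 0.0, "withinB": 0.0, "cross": 1.0}
        assert part.mean_cross_fraction_a == pytest.approx(1.0)

    def test_outside_edges_ignored_and_counted(self):
        part = interaction_partition(
            _edge_bundle([("a1", "zz"), ("a1", "a2")]), {"a1", "a2"}, {"b1"}
        )
        assert part.n_ignored_edges == 1 and part.n_retained == 1

    def test_partition_conserves_edge_count(self):
        edges = [("a1", "a2"), ("a1", "b1"), ("b1", "b2"), ("a2", "b2"), ("a1", "x")]
        part = interaction_partition(_edge_bundle(edges), {"a1", "a2"}, {"b1", "b2"})
        assert part.within_a + part.within_b + part.cross == len(edges) - 1

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            interaction_partition(_edge_bundle([]), {"a"}, {"a"})


class TestScreens:
    def _bundle(self, omim=None, flags=None):
        return AnnotationBundle(
            categories={},
            phenotypes={},
            has_rnai_data=frozenset(),
            expression_text={},
            interactions=frozenset(),
            omim_map_key=omim or {},
            characterized_flags=flags or {},
        )

    def test_disease_filter_keeps_map_key_three(self):
        bundle = self._bundle(omim={"g1": 3, "g2": 2})
        assert disease_filter(bundle, {"g1", "g2", "g3"}) == {"g1"}
        assert disease_filter(self._bundle(), {"g1"}) == frozenset()
        all3 = self._bundle(omim={"g1": 3, "g2": 3})
        assert disease_filter(all3, {"g1", "g2"}) == {"g1", "g2"}

    def test_uncharacterized_requires_all_sources_silent(self):
        flags = {
            "g1": (False, False, False),
            "g2": (True, False, False),
            "g3": (False, True, False),
        }
        assert flag_uncharacterized(self._bundle(flags=flags), set(flags)) == {"g1"}
        assert flag_uncharacterized(self._bundle(flags=flags), set()) == frozenset()

    def test_missing_flags_is_hard_error(self):
        with pytest.raises(KeyError, match="gX"):
            flag_uncharacterized(self._bundle(flags={}), {"gX"})


def test_bundle_round_trip(tmp_path):
    bundle = AnnotationBundle(
        categories={"g1": frozenset({"A", "B"}), "g2": frozenset({"A"})},
        phenotypes={"g1": frozenset({"Emb", "Unc"})},
        has_rnai_data=frozenset({"g1", "g2"}),
        expression_text={"g1": "head neurons; gonad sheath"},
        interactions=frozenset({frozenset({"g1", "g2"})}),
        omim_map_key={"g1": 3, "g2": 1},
        characterized_flags={"g1": (True, False, True), "g2": (False, False, False)},
    )
    write_annotation_bundle(bundle, tmp_path)
    assert read_annotation_bundle(tmp_path) == bundle
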