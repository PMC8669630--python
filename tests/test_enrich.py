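"""Hypergeometric network score, Fisher identity, annotation and reporting.

Expected values in the example tests were computed with an exact
rational-arithmetic oracle (``_exact_tail`` below) and frozen.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import deathnet as dn
from deathnet.errors import ContractError


def _exact_tail(N: int, G: int, s: int, f: int) -> Fraction:
    """Brute-force P(X >= f) by exact rational pmf summation."""
    total = Fraction(0)
    denom = math.comb(N, s)
    for i in range(f, min(G, s) + 1):
        total += Fraction(math.comb(G, i) * math.comb(N - G, s - i), denom)
    return min(total, Fraction(1))


class TestNetworkScore:
    def test_zero_overlap_gives_p_one(self):
        p, score = dn.network_score(10, 4, 3, 0)
        assert p == 1.0
        assert score == 0.0

    def test_small_example_is_one_third(self):
        # exact oracle: P(X >= 2 | N=10, G=4, s=3) = 1/3
        assert _exact_tail(10, 4, 3, 2) == Fraction(1, 3)
        p, score = dn.network_score(10, 4, 3, 2)
        assert p == pytest.approx(1 / 3, rel=1e-12)
        assert score == pytest.approx(-math.log10(1 / 3), rel=1e-12)

    def test_score_threshold_closed_form(self):
        # the inclusion threshold: score 4 corresponds exactly to p = 1e-4
        assert -math.log10(1e-4) == 4.0
        assert not dn.passes_threshold(1e-4)
        assert dn.passes_threshold(0.99e-4)
        assert not dn.passes_threshold(1.01e-4)

    def test_matches_exact_oracle_on_random_small_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            N = int(rng.integers(1, 26))
            G = int(rng.integers(0, N + 1))
            s = int(rng.integers(0, N + 1))
            f = int(rng.integers(0, min(G, s) + 1))
            p, _ = dn.network_score(N, G, s, f)
            exact = float(_exact_tail(N, G, s, f))
            assert p == pytest.approx(exact, rel=1e-12, abs=1e-300)

    def test_extreme_tail_stays_finite_in_log_space(self):
        # overlap deep in the tail: the score must stay finite, large and
        # correct to ~1e-9 relative against exact big-integer rationals
        def log10_big(n: int) -> float:
            shift = max(0, n.bit_length() - 60)
            return math.log10(n >> shift) + shift * math.log10(2)

        N, G, s, f = 20000, 500, 500, 250
        p, score = dn.network_score(N, G, s, f)
        assert p >= 1e-320
        exact = _exact_tail(N, G, s, f)
        expected = -(log10_big(exact.numerator) - log10_big(exact.denominator))
        assert score > 250
        assert score == pytest.approx(expected, rel=1e-9)

    def test_precondition_violations_name_the_inequality(self):
        with pytest.raises(ContractError, match="f <= min"):
            dn.network_score(10, 4, 3, 4)
        with pytest.raises(ContractError, match="G <= N"):
            dn.network_score(3, 4, 3, 1)
        with pytest.raises(ContractError, match="s <= N"):
            dn.network_score(4, 4, 5, 1)
        with pytest.raises(ContractError, match="non-negative"):
            dn.EnrichmentInput(N=10, G=-1, s=3, f=0)

    @given(
        st.integers(min_value=1, max_value=80).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(min_value=0, max_value=N),
                st.integers(min_value=0, max_value=N),
            )
        ),
        st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_score_monotone_in_overlap(self, nga, data):
        N, G, s = nga
        fmax = min(G, s)
        f = data.draw(st.integers(min_value=0, max_value=fmax))
        _, sc_f = dn.network_score(N, G, s, f)
        if f < fmax:
            _, sc_next = dn.network_score(N, G, s, f + 1)
            assert sc_next >= sc_f - 1e-12


class TestFisherIdentity:
    @given(
        st.integers(min_value=1, max_value=120).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(min_value=0, max_value=N),
                st.integers(min_value=0, max_value=N),
            )
        ),
        st.data(),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_fisher_equals_hypergeometric_tail(self, nga, data):
        N, G, s = nga
        f = data.draw(st.integers(min_value=0, max_value=min(G, s)))
        inp = dn.EnrichmentInput(N=N, G=G, s=s, f=f)
        p_tail, _ = dn.network_score(inp)
        p_fisher = dn.fisher_enrichment(inp)
        assert abs(p_tail - p_fisher) < 1e-12

    def test_two_by_two_example(self):
        # table [[2, 2], [1, 5]] from N=10, G=4, s=3, f=2
        inp = dn.EnrichmentInput(N=10, G=4, s=3, f=2)
        assert dn.fisher_enrichment(inp) == pytest.approx(1 / 3, rel=1e-12)

    def test_zero_overlap(self):
        assert dn.fisher_enrichment(dn.EnrichmentInput(N=10, G=4, s=3, f=0)) == 1.0


class TestAnnotateModules:
    def test_whole_universe_pathway_cannot_enrich(self):
        net = dn.MultilayerNetwork()
        genes = ["a", "b", "c", "d"]
        for i in range(4):
            for j in range(i + 1, 4):
                net.add_edge(dn.TypedEdge(genes[i], genes[j], "PP"))
        part = dn.ModulePartition({g: 1 for g in genes}, k=1)
        sets = dn.GeneSetCollection({"ALL": ("everything", set(genes))})
        for mode in ("edges", "genes"):
            (rec,) = dn.annotate_modules(part, net, sets, element_mode=mode)
            assert rec.input.N == rec.input.G == rec.input.s == rec.input.f
            assert rec.p_value == 1.0
            assert rec.score == 0.0

    def test_toy_edge_mode_matches_hand_enumeration(self, toy_reference):
        # module {g1,g2,g3} has 3 internal reference edges; the pathway
        # covering those genes induces the same 3 of N=7 edges, so
        # p = C(3,3)C(4,0)/C(7,3) = 1/35 (exact oracle _exact_tail)
        assert _exact_tail(7, 3, 3, 3) == Fraction(1, 35)
        part = dn.ModulePartition(
            {"g1": 1, "g2": 1, "g3": 1, "g4": 2, "g5": 2, "g6": 2}, k=2
        )
        sets = dn.GeneSetCollection({"P": ("toy", {"g1", "g2", "g3"})})
        rec1, rec2 = dn.annotate_modules(part, toy_reference, sets, element_mode="edges")
        assert (rec1.input.N, rec1.input.G, rec1.input.s, rec1.input.f) == (7, 3, 3, 3)
        assert rec1.p_value == pytest.approx(1 / 35, rel=1e-12)
        # module 2 has internal edges g4-g5, g5-g6, g4-g6 but zero overlap
        assert rec2.input.f == 0
        assert rec2.p_value == 1.0

    def test_toy_gene_mode(self, toy_reference):
        part = dn.ModulePartition(
            {"g1": 1, "g2": 1, "g3": 1, "g4": 2, "g5": 2, "g6": 2}, k=2
        )
        sets = dn.GeneSetCollection({"P": ("toy", {"g1", "g2", "g3"})})
        rec1, _ = dn.annotate_modules(part, toy_reference, sets, element_mode="genes")
        # p = 1/C(6,3) = 1/20
        assert rec1.p_value == pytest.approx(1 / 20, rel=1e-12)

    def test_pathway_absent_from_universe_reported_not_dropped(self, toy_reference):
        part = dn.ModulePartition({f"g{i}": 1 for i in range(1, 7)}, k=1)
        sets = dn.GeneSetCollection({"GHOST": ("absent", {"zz1", "zz2"})})
        (rec,) = dn.annotate_modules(part, toy_reference, sets, element_mode="genes")
        assert rec.input.s == 0
        assert rec.p_value == 1.0

    def test_partition_outside_universe_errors(self, toy_reference):
        part = dn.ModulePartition({"nope": 1}, k=1)
        sets = dn.GeneSetCollection({"P": ("x", {"g1"})})
        with pytest.raises(ContractError):
            dn.annotate_modules(part, toy_reference, sets)

    def test_qvalues_are_bh_adjusted(self, toy_reference):
        from statsmodels.stats.multitest import multipletests

        part = dn.ModulePartition(
            {"g1": 1, "g2": 1, "g3": 1, "g4": 2, "g5": 2, "g6": 2}, k=2
        )
        sets = dn.GeneSetCollection(
            {"P1": ("a", {"g1", "g2", "g3"}), "P2": ("b", {"g4", "g5"})}
        )
        recs = dn.annotate_modules(part, toy_reference, sets, element_mode="genes")
        expected = multipletests([r.p_value for r in recs], method="fdr_bh")[1]
        assert [r.q_value for r in recs] == pytest.approx(list(expected))

    def test_planted_enrichment_recovered(self):
        cfg = dn.SynthConfig(n_genes=200, k_true=8, p_in=0.3, p_out=0.01, seed=3, n_sets=12)
        net, truth = dn.simulate_multilayer(cfg)
        sets, planted = dn.simulate_genesets(truth, cfg)
        recs = dn.annotate_modules(truth, net, sets, element_mode="genes")
        by_pair = {(r.module, r.pathway): r for r in recs}
        assert all(by_pair[pair].passed for pair in planted)


class TestAnnotationMatrix:
    def test_gene_in_no_term_has_zero_row(self):
        sets = dn.GeneSetCollection({"T1": ("x", {"a"})})
        mat = dn.build_annotation_matrix(["a", "zzz"], sets)
        assert mat.row_profile("zzz").sum() == 0
        assert mat.row_profile("a").sum() == 1

    def test_disjoint_terms_identity_pattern(self):
        sets = dn.GeneSetCollection({"T1": ("x", {"a"}), "T2": ("y", {"b"})})
        mat = dn.build_annotation_matrix(["a", "b"], sets)
        assert np.array_equal(mat.data, np.eye(2, dtype=np.int8))

    def test_pair_requires_both_endpoints(self):
        sets = dn.GeneSetCollection({"T": ("x", {"g1", "g3"})})
        mat = dn.build_annotation_matrix([("g1", "g2"), ("g1", "g3")], sets)
        assert mat.row_profile(("g1", "g2"))[0] == 0
        assert mat.row_profile(("g1", "g3"))[0] == 1

    def test_marginals_equal_recomputed_intersections(self):
        cfg = dn.SynthConfig(n_genes=60, k_true=4, p_in=0.4, p_out=0.02, seed=9, n_sets=6)
        net, truth = dn.simulate_multilayer(cfg)
        sets, _ = dn.simulate_genesets(truth, cfg)
        genes = net.gene_symbols
        mat = dn.build_annotation_matrix(genes, sets)
        col_sums = mat.data.sum(axis=0)
        for j, name in enumerate(mat.columns):
            assert col_sums[j] == len(sets.genes_canon(name) & {g.upper() for g in genes})

    def test_mode_columns_appended(self):
        sets = dn.GeneSetCollection({"T": ("x", {"a"})})
        mat = dn.build_annotation_matrix(
            ["a", "b"], sets, mode_labels={"apoptosis": {"a", "b"}}
        )
        assert mat.columns == ["T", "apoptosis"]
        assert mat.row_profile("b").tolist() == [0, 1]


class TestComposeAndReport:
    def _records(self, toy_reference, threshold=0.5):
        part = dn.ModulePartition(
            {"g1": 1, "g2": 1, "g3": 1, "g4": 2, "g5": 2, "g6": 2}, k=2
        )
        sets = dn.GeneSetCollection(
            {"P1": ("a", {"g1", "g2", "g3"}), "P2": ("b", {"g3", "g4", "g5", "g6"})}
        )
        return dn.annotate_modules(
            part, toy_reference, sets, element_mode="edges", threshold=threshold
        ), sets

    def test_single_passing_pathway_induces_its_subgraph(self, toy_reference):
        recs, sets = self._records(toy_reference)
        only_p1 = [r for r in recs if r.pathway == "P1"]
        comp = dn.compose_network(only_p1, sets, toy_reference)
        assert comp.edge_pairs() == {("G1", "G2"), ("G1", "G3"), ("G2", "G3")}

    def test_union_of_overlapping_pathways_has_no_duplicates(self, toy_reference):
        recs, sets = self._records(toy_reference)
        comp = dn.compose_network(recs, sets, toy_reference)
        expected = toy_reference.induced_pairs({"g1", "g2", "g3"}) | toy_reference.induced_pairs(
            {"g3", "g4", "g5", "g6"}
        )
        assert comp.edge_pairs() == expected

    def test_threshold_above_all_scores_gives_empty_composite(self, toy_reference, caplog):
        recs, sets = self._records(toy_reference, threshold=1000.0)
        with caplog.at_level("WARNING"):
            comp = dn.compose_network(recs, sets, toy_reference)
        assert comp.n_edges() == 0

    def test_top_k_defaults_to_25(self):
        recs = [
            dn.EnrichmentRecord(
                module=1,
                pathway=f"P{i:02d}",
                input=dn.EnrichmentInput(N=100, G=10, s=10, f=0),
                p_value=1.0 / (i + 1),
                score=float(i),
                passed=False,
            )
            for i in range(30)
        ]
        df = dn.report_top(recs)
        assert len(df) == 25
        assert df.iloc[0]["pathway"] == "P29"

    def test_fewer_records_than_top_k(self):
        recs = [
            dn.EnrichmentRecord(
                module=1,
                pathway=f"P{i}",
                input=dn.EnrichmentInput(N=10, G=2, s=2, f=0),
                p_value=1.0,
                score=0.0,
                passed=False,
            )
            for i in range(3)
        ]
        assert len(dn.report_top(recs)) == 3

    def test_equal_scores_ordered_by_name(self):
        recs = [
            dn.EnrichmentRecord(
                module=1,
                pathway=name,
                input=dn.EnrichmentInput(N=10, G=2, s=2, f=0),
                p_value=0.5,
                score=0.301,
                passed=False,
            )
            for name in ("B_PATH", "A_PATH")
        ]
        df = dn.report_top(recs)
        assert list(df["pathway"]) == ["A_PATH", "B_PATH"]
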