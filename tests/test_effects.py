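"""Causal-effect aggregation semantics, path identities and the mixed graph."""

import numpy as np
import pytest

from dissonet.dag import WeightedDag, enumerate_path_effects
from dissonet.dagmcmc import DagSampleSet
from dissonet.effects import (
    aggregate_effects,
    effects_table,
    fit_path_coefficients,
    mediator_share,
    mixed_graph,
    total_effect,
)
from dissonet.synthetic import sample_random_dag, simulate_construct_scores


def _sample_set(labels, dags):
    return DagSampleSet(labels, dags, len(dags), 0, 1, 0, [0.0] * len(dags), {})


@pytest.fixture(scope="module")
def abc_data():
    """Data generated from A -> B (0.5) -> C (0.5), standardized."""
    dag = WeightedDag(["A", "B", "C"], [("A", "B"), ("B", "C")],
                      {("A", "B"): 0.5, ("B", "C"): 0.5})
    X = simulate_construct_scores(dag, 5000, seed=0).to_numpy()
    return (X - X.mean(0)) / X.std(0)


class TestFitPathCoefficients:
    def test_single_edge_recovers_coefficient(self):
        dag = WeightedDag(["A", "B"], [("A", "B")], {("A", "B"): 0.5})
        X = simulate_construct_scores(dag, 20_000, seed=1).to_numpy()
        X = (X - X.mean(0)) / X.std(0)
        fitted = fit_path_coefficients(dag, X)
        # standardization shrinks the raw 0.5 coefficient by sd(B) = sqrt(1.25)
        assert fitted.weights[("A", "B")] == pytest.approx(0.5 / np.sqrt(1.25), abs=0.02)

    def test_empty_dag_has_no_coefficients(self, abc_data):
        fitted = fit_path_coefficients((0, 0, 0), abc_data, labels=["A", "B", "C"])
        assert fitted.edges == [] and fitted.weights == {}

    def test_matches_brute_force_normal_equations(self, abc_data):
        # node C regressed on {A, B} by an independent solver
        fitted = fit_path_coefficients((0, 1, 3), abc_data, labels=["A", "B", "C"])
        Z = abc_data
        design = Z[:, [0, 1]]
        beta = np.linalg.pinv(design.T @ design) @ design.T @ Z[:, 2]
        assert fitted.weights[("A", "C")] == pytest.approx(beta[0], abs=1e-8)
        assert fitted.weights[("B", "C")] == pytest.approx(beta[1], abs=1e-8)

    def test_collinear_parents_warn(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        Z = np.column_stack([x, x, rng.standard_normal(200)])
        with pytest.warns(UserWarning, match="collinear"):
            fit_path_coefficients((0, 0, 3), Z, labels=["A", "B", "C"])


class TestTotalEffect:
    def test_chain_product(self, chain_dag):
        assert total_effect(chain_dag, "A", "C") == pytest.approx(0.25)

    def test_no_path_is_zero(self, chain_dag):
        assert total_effect(chain_dag, "C", "A") == 0.0

    def test_same_node_rejected(self, chain_dag):
        with pytest.raises(ValueError):
            total_effect(chain_dag, "A", "A")

    def test_matrix_equals_enumeration_on_random_dags(self):
        for seed in range(25):
            dag = sample_random_dag(10, 0.35, seed=seed)
            src, dst = dag.nodes[0], dag.nodes[-1]
            assert total_effect(dag, src, dst) == pytest.approx(
                enumerate_path_effects(dag, src, dst), abs=1e-10
            )


class TestAggregateEffects:
    def test_four_dag_fixture_reproduces_hand_computation(self, abc_data):
        # 3 of 4 DAGs contain A->B (as part of different structures), 1 does not
        labels = ["A", "B", "C"]
        dags = [
            (0, 1, 0),  # A->B
            (0, 1, 2),  # A->B->C
            (0, 1, 1),  # A->B, A->C
            (0, 0, 2),  # B->C only: no A-B pathway
        ]
        samples = _sample_set(labels, dags)
        summary = aggregate_effects(samples, abc_data, "A", "B")
        assert summary.pathway_present_pct == pytest.approx(75.0)
        assert summary.direct_edge_pct == pytest.approx(100.0)
        # conditional mean equals the mean of the three per-DAG OLS slopes,
        # which here are identical (same regression in each structure)
        Z = abc_data
        slope = (Z[:, 0] @ Z[:, 1]) / (Z[:, 0] @ Z[:, 0])
        assert summary.causal_effect == pytest.approx(slope, abs=1e-10)
        assert summary.ci90[0] <= summary.causal_effect <= summary.ci90[1]

    def test_direct_share_is_relative_to_pathway_present_subset(self, abc_data):
        # pathway A->C present in 2 of 4 DAGs; direct edge in 1 of those 2:
        # the published reading (57.96% pathways, 64.08% "of those" direct)
        labels = ["A", "B", "C"]
        dags = [
            (0, 1, 2),  # A->B->C: pathway, no direct edge
            (0, 0, 1),  # A->C: pathway, direct
            (0, 0, 0),  # empty
            (0, 1, 0),  # A->B only
        ]
        summary = aggregate_effects(_sample_set(labels, dags), abc_data, "A", "C")
        assert summary.pathway_present_pct == pytest.approx(50.0)
        assert summary.direct_edge_pct == pytest.approx(50.0)

    def test_no_pathway_yields_absent_fields(self, abc_data):
        samples = _sample_set(["A", "B", "C"], [(0, 0, 0), (0, 0, 2)])
        summary = aggregate_effects(samples, abc_data, "A", "B")
        assert summary.pathway_present_pct == 0.0
        assert summary.causal_effect is None and summary.ci90 is None
        assert summary.direct_edge_pct is None

    def test_acyclicity_forbids_bidirectional_paths(self, abc_data):
        labels = ["A", "B", "C"]
        dags = [(0, 1, 2), (2, 0, 2), (0, 4, 0), (0, 0, 3)]
        samples = _sample_set(labels, dags)
        for x, y in [("A", "B"), ("A", "C"), ("B", "C")]:
            fwd = aggregate_effects(samples, abc_data, x, y).pathway_present_pct
            rev = aggregate_effects(samples, abc_data, y, x).pathway_present_pct
            assert fwd + rev <= 100.0 + 1e-12

    def test_effects_table_shape(self, abc_data):
        samples = _sample_set(["A", "B", "C"], [(0, 1, 2), (0, 1, 0)])
        table = effects_table(samples, abc_data, "A")
        assert len(table) == 4  # both directions for each of the 2 other nodes
        assert set(table.columns) >= {
            "source", "target", "pathway_present_pct", "causal_effect",
            "ci90_lo", "ci90_hi", "direct_edge_pct", "direct_causal_effect",
        }


class TestMediatorShare:
    def test_pure_chain_is_fully_mediated(self, abc_data):
        samples = _sample_set(["A", "B", "C"], [(0, 1, 2)])
        assert mediator_share(samples, abc_data, "A", "C", "B") == 100.0

    def test_parallel_edge_not_mediated(self, abc_data):
        samples = _sample_set(["A", "B", "C"], [(0, 0, 1)])  # A->C direct only
        assert mediator_share(samples, abc_data, "A", "C", "B") == 0.0

    def test_mixed_fixture_matches_hand_count(self, abc_data):
        labels = ["A", "B", "C"]
        dags = (
            [(0, 1, 2)] * 4       # A->B->C: mediated
            + [(0, 0, 1)] * 3     # A->C only: not mediated
            + [(0, 1, 3)] * 2     # A->B, A->C, B->C: mediated (A->B->C exists)
            + [(0, 0, 0)]         # no pathway at all
        )
        samples = _sample_set(labels, dags)
        # 9 pathway-present DAGs, 6 of them pass through B
        assert mediator_share(samples, abc_data, "A", "C", "B") == pytest.approx(
            100 * 6 / 9
        )

    def test_mediator_must_differ(self, abc_data):
        samples = _sample_set(["A", "B", "C"], [(0, 1, 2)])
        with pytest.raises(ValueError):
            mediator_share(samples, abc_data, "A", "C", "A")


class TestMixedGraph:
    def test_unanimous_sample_fully_arrowed(self):
        dags = [(0, 1, 2)] * 10
        g = mixed_graph(_sample_set(["A", "B", "C"], dags))
        assert set(g.directed_edges) == {("A", "B"), ("B", "C")}
        assert g.undirected_edges == []

    def test_orientation_split_stays_undirected(self):
        # edge present in 60% of DAGs, orientations split 50/50
        dags = [(0, 1, 0)] * 3 + [(2, 0, 0)] * 3 + [(0, 0, 0)] * 4
        g = mixed_graph(_sample_set(["A", "B", "C"], dags))
        assert g.undirected_edges == [("A", "B")]
        assert g.directed_edges == []
        assert g.inclusion_freq[("A", "B")] == pytest.approx(0.6)

    def test_inclusion_threshold_is_strict(self):
        # exactly 50% inclusion must be dropped ("over 50%")
        dags = [(0, 1, 0)] * 5 + [(0, 0, 0)] * 5
        g = mixed_graph(_sample_set(["A", "B", "C"], dags))
        assert g.undirected_edges == [] and g.directed_edges == []

    def test_direction_threshold_is_strict(self):
        # 9 of 10 orientations agree: exactly 0.90 is not "over 90%"
        dags = [(0, 1, 0)] * 9 + [(2, 0, 0)]
        g = mixed_graph(_sample_set(["A", "B", "C"], dags))
        assert g.undirected_edges == [("A", "B")]
        dags = [(0, 1, 0)] * 19 + [(2, 0, 0)]  # 95% > 90%: arrowed
        g = mixed_graph(_sample_set(["A", "B", "C"], dags))
        assert g.directed_edges == [("A", "B")]

    def test_twenty_dag_fixture_matches_hand_computation(self):
        labels = ["A", "B", "C"]
        dags = (
            [(0, 1, 2)] * 11      # A->B, B->C
            + [(2, 0, 2)] * 5     # B->A, B->C
            + [(0, 0, 3)] * 3     # A->C, B->C
            + [(0, 0, 0)]
        )
        g = mixed_graph(_sample_set(labels, dags))
        # A-B: 16/20 = 80% > 50%; orientation A->B 11/16 = 68.75% -> undirected
        # B-C: 19/20 = 95%; all B->C -> directed
        # A-C: 3/20 -> dropped
        assert g.undirected_edges == [("A", "B")]
        assert g.directed_edges == [("B", "C")]
        assert g.direction_freq[("B", "C")] == pytest.approx(1.0)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            mixed_graph(_sample_set(["A"], [(0,)]), edge_threshold=0.0)
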