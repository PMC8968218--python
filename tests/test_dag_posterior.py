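"""BGe scoring, MCMC samplers, exact oracles and persistence."""

import itertools

import numpy as np
import pytest

from dissonet.bge import BgeScore, ScoreConfig
from dissonet.dagmcmc import (
    DagSampleSet,
    _is_acyclic,
    convergence_diagnostics,
    load_samples,
    sample_dags,
    save_samples,
)
from dissonet.exact import exact_edge_posterior

from conftest import make_dependent_data


def _all_dags(p):
    for masks in itertools.product(
        *[[m for m in range(1 << p) if not (m >> j & 1)] for j in range(p)]
    ):
        if _is_acyclic(masks):
            yield masks


def _random_dag_masks(p, rng, density=0.4):
    order = rng.permutation(p)
    masks = [0] * p
    for a in range(p):
        for b in range(a + 1, p):
            if rng.random() < density:
                masks[order[b]] |= 1 << order[a]
    return tuple(int(m) for m in masks)


def _covered_edges(masks):
    """Edges u->v with pa(v) = pa(u) + {u} (reversal preserves the
    Markov-equivalence class)."""
    out = []
    for v, m in enumerate(masks):
        mm = m
        while mm:
            u = (mm & -mm).bit_length() - 1
            mm &= mm - 1
            if masks[v] & ~(1 << u) == masks[u]:
                out.append((u, v))
    return out


class TestBgeScore:
    def test_score_equivalence_over_covered_edge_reversals(self):
        rng = np.random.default_rng(0)
        X = make_dependent_data(400, 8, seed=1)
        sc = BgeScore(X)
        checked = 0
        while checked < 100:
            masks = list(_random_dag_masks(8, rng))
            for u, v in _covered_edges(masks):
                rev = list(masks)
                rev[v] = masks[v] & ~(1 << u)
                rev[u] = masks[u] | (1 << v)
                assert _is_acyclic(rev)
                assert sc.dag_score(tuple(rev)) == pytest.approx(
                    sc.dag_score(tuple(masks)), abs=1e-8
                )
                checked += 1
        assert checked >= 100

    def test_bivariate_orientation_equivalence(self):
        X = make_dependent_data(500, 2, seed=2)
        sc = BgeScore(X)
        assert sc.dag_score((0, 1)) == pytest.approx(sc.dag_score((2, 0)), abs=1e-9)

    def test_occam_prefers_no_parent_under_independence(self):
        X = np.random.default_rng(3).standard_normal((5000, 2))
        sc = BgeScore(X)
        assert sc.local_score(0, 0) > sc.local_score(0, 2)

    def test_cache_is_transparent(self):
        X = make_dependent_data(300, 4, seed=4)
        a, b = BgeScore(X), BgeScore(X)
        v1 = a.local_score(2, 0b0011)
        v2 = a.local_score(2, 0b0011)  # cached
        assert v1 == v2 == b.local_score(2, 0b0011)

    def test_self_parent_rejected(self):
        sc = BgeScore(make_dependent_data(100, 3, seed=5))
        with pytest.raises(ValueError):
            sc.local_score(1, 0b010)

    def test_edge_penalty_is_modular(self):
        X = make_dependent_data(300, 3, seed=6)
        plain = BgeScore(X, ScoreConfig())
        pen = BgeScore(X, ScoreConfig(edge_penalty=-2.0))
        masks = (0, 1, 3)  # 2 edges into node 2? masks: node1<-node0, node2<-{0,1}
        n_edges = sum(int(m).bit_count() for m in masks)
        assert pen.dag_score(masks) == pytest.approx(
            plain.dag_score(masks) - 2.0 * n_edges, abs=1e-9
        )


class TestExactPosterior:
    def test_uniform_prior_matches_enumeration_p4(self):
        X = make_dependent_data(300, 4, seed=7)
        sc = BgeScore(X)
        dags = list(_all_dags(4))
        scores = np.array([sc.dag_score(d) for d in dags])
        w = np.exp(scores - scores.max())
        E = np.zeros((4, 4))
        for d, wi in zip(dags, w):
            for v, m in enumerate(d):
                while m:
                    u = (m & -m).bit_length() - 1
                    E[u, v] += wi
                    m &= m - 1
        np.testing.assert_allclose(
            exact_edge_posterior(sc, prior="uniform"), E / w.sum(), atol=1e-10
        )

    def test_order_modular_matches_order_enumeration_p4(self):
        from dissonet.exact import _weight_tables, _zeta

        X = make_dependent_data(250, 4, seed=8)
        sc = BgeScore(X)
        a = _weight_tables(sc)
        A = _zeta(a, 4)
        num = np.zeros((4, 4))
        Z = 0.0
        for order in itertools.permutations(range(4)):
            pred, wprod, preds = 0, 1.0, {}
            for j in order:
                preds[j] = pred
                wprod *= A[j, pred]
                pred |= 1 << j
            Z += wprod
            for v in range(4):
                for u in range(4):
                    if u != v and preds[v] >> u & 1:
                        num[u, v] += wprod / A[v, preds[v]] * (
                            A[v, preds[v]] - A[v, preds[v] ^ (1 << u)]
                        )
        np.testing.assert_allclose(
            exact_edge_posterior(sc, prior="order_modular"), num / Z, atol=1e-10
        )

    def test_p2_equals_three_dag_enumeration(self):
        X = make_dependent_data(500, 2, seed=9)
        sc = BgeScore(X)
        s_empty = sc.dag_score((0, 0))
        s_fwd = sc.dag_score((0, 1))
        s_rev = sc.dag_score((2, 0))
        w = np.exp(np.array([s_empty, s_fwd, s_rev]) - s_fwd)
        expected_fwd = w[1] / w.sum()
        P = exact_edge_posterior(sc, prior="uniform")
        assert P[0, 1] == pytest.approx(expected_fwd, abs=1e-12)
        assert P[1, 0] == pytest.approx(w[2] / w.sum(), abs=1e-12)

    @pytest.mark.parametrize("prior", ["uniform", "order_modular"])
    def test_orientations_mutually_exclusive(self, prior):
        X = make_dependent_data(300, 4, seed=10)
        P = exact_edge_posterior(X, prior=prior)
        assert np.all(P + P.T <= 1 + 1e-12)
        assert np.all(np.diag(P) == 0)

    def test_independent_columns_have_low_edge_probability(self):
        X = np.random.default_rng(11).standard_normal((2000, 4))
        P = exact_edge_posterior(X, prior="uniform")
        assert P.max() < 0.05

    def test_refuses_large_p(self):
        X = np.random.default_rng(12).standard_normal((50, 12))
        with pytest.raises(ValueError, match="exceeds"):
            exact_edge_posterior(X, prior="uniform")


class TestSamplers:
    def test_single_node_posterior_is_trivial(self):
        X = np.random.default_rng(13).standard_normal((100, 1))
        s = sample_dags(X, iterations=2000, seed=0, sampler="edge_mh")
        assert all(d == (0,) for d in s.dags)

    def test_strong_bivariate_dependence_forces_edge(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(2000)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(2000)
        X = np.column_stack([x, y])
        s = sample_dags(X, iterations=50_000, seed=1, sampler="partition")
        F = s.edge_frequency_matrix()
        assert F[0, 1] + F[1, 0] > 0.99

    @pytest.mark.parametrize("sampler", ["edge_mh", "partition"])
    def test_matches_exact_posterior(self, sampler):
        X = make_dependent_data(300, 4, seed=15)
        exact = exact_edge_posterior(X, prior="uniform")
        s = sample_dags(X, iterations=120_000, seed=2, sampler=sampler)
        assert np.max(np.abs(s.edge_frequency_matrix() - exact)) < 0.05

    def test_retained_count_and_acyclicity(self):
        X = make_dependent_data(200, 5, seed=16)
        s = sample_dags(X, iterations=10_000, burn_in=2_000, thinning=4, seed=3,
                        sampler="partition")
        assert len(s) == (10_000 - 2_000) // 4
        assert all(_is_acyclic(d) for d in s.dags)
        assert all(np.isfinite(s.score_trace))

    def test_seed_determinism(self):
        X = make_dependent_data(200, 4, seed=17)
        a = sample_dags(X, iterations=20_000, seed=4, sampler="partition")
        b = sample_dags(X, iterations=20_000, seed=4, sampler="partition")
        assert a.dags == b.dags and a.score_trace == b.score_trace

    def test_overwhelming_edge_penalty_empties_posterior(self):
        X = make_dependent_data(300, 4, seed=18)
        s = sample_dags(X, iterations=30_000, seed=5, sampler="edge_mh",
                        cfg=ScoreConfig(edge_penalty=-200.0))
        empties = sum(1 for d in s.dags if all(m == 0 for m in d))
        assert empties / len(s) > 0.99

    def test_unknown_sampler_rejected(self):
        X = make_dependent_data(100, 3, seed=19)
        with pytest.raises(ValueError, match="sampler"):
            sample_dags(X, iterations=1000, seed=0, sampler="gibbs")


class TestDiagnostics:
    def test_identical_seeds_give_zero_gap(self):
        X = make_dependent_data(200, 4, seed=20)
        a = sample_dags(X, iterations=20_000, seed=6)
        b = sample_dags(X, iterations=20_000, seed=6)
        d = convergence_diagnostics(a, b)
        assert d["max_edge_frequency_gap"] == 0.0 and not d["flagged"]

    def test_converged_chains_agree(self):
        X = make_dependent_data(300, 5, seed=21)
        a = sample_dags(X, iterations=150_000, seed=7)
        b = sample_dags(X, iterations=150_000, seed=8)
        assert not convergence_diagnostics(a, b)["flagged"]

    def test_undersampled_chains_flagged(self):
        X = make_dependent_data(400, 6, seed=22)
        a = sample_dags(X, iterations=400, burn_in=100, thinning=1, seed=9)
        b = sample_dags(X, iterations=400, burn_in=100, thinning=1, seed=10)
        assert convergence_diagnostics(a, b)["flagged"]

    def test_mismatched_configs_refused(self):
        X = make_dependent_data(200, 3, seed=23)
        a = sample_dags(X, iterations=5000, seed=11)
        b = sample_dags(X, iterations=6000, seed=11)
        with pytest.raises(ValueError, match="refused"):
            convergence_diagnostics(a, b)


class TestPersistence:
    def test_round_trip_bit_exact(self, tmp_path):
        X = make_dependent_data(200, 5, seed=24)
        s = sample_dags(X, iterations=20_000, seed=12, sampler="partition")
        path = tmp_path / "samples.txt"
        save_samples(s, path)
        back = load_samples(path)
        assert back.dags == s.dags
        assert back.labels == s.labels
        assert back.score_trace == pytest.approx(s.score_trace)
        assert back.meta == s.meta

    def test_empty_dag_line_round_trip(self, tmp_path):
        s = DagSampleSet(["a", "b"], [(0, 0), (0, 1)], 10, 0, 5, 0, [0.0, 0.0], {})
        path = tmp_path / "samples.txt"
        save_samples(s, path)
        assert load_samples(path).dags == s.dags
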