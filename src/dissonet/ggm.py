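"""Undirected partial-correlation network estimation.

The estimator mirrors the unregularized-model-selection approach favoured
for very large samples: a graphical-lasso penalty path proposes ~100
candidate sparsity patterns; each pattern is re-fitted *without* penalty by
constrained maximum likelihood and scored by the extended BIC; the best
candidate then seeds a best-first stepwise search over single-edge additions
and removals until no move strictly improves the EBIC.  Edge weights of the
selected model are partial correlations ``r_ij = -K_ij / sqrt(K_ii K_jj)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._ggm_kernels import ggm_refit, glasso_pattern

__all__ = [
    "PartialCorrelationNetwork",
    "GgmConvergenceError",
    "fit_ggm_given_structure",
    "gaussian_loglik",
    "ebic_score",
    "ggm_model_select",
    "centrality",
]


class GgmConvergenceError(RuntimeError):
    def __init__(self, residual: float):
        super().__init__(f"constrained MLE did not converge (residual {residual:.3e})")
        self.residual = residual


@dataclass
class PartialCorrelationNetwork:
    """Symmetric weighted network of partial correlations."""

    labels: list[str]
    weights: np.ndarray  # p x p, zero diagonal
    precision: np.ndarray
    ebic: float
    gamma: float
    ebic_trace: list[float] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def edges(self) -> set[tuple[str, str]]:
        out = set()
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.weights[i, j] != 0.0:
                    out.add((self.labels[i], self.labels[j]))
        return out

    def adjacency(self) -> np.ndarray:
        return self.weights != 0.0

    def edge_vector(self) -> np.ndarray:
        """Upper-triangular weights flattened row-major (length p(p-1)/2)."""
        return self.weights[np.triu_indices(self.p, 1)]

    def to_graph(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.labels)
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0:
                    G.add_edge(self.labels[i], self.labels[j], weight=float(w), length=1.0 / abs(w))
        return G


def fit_ggm_given_structure(
    S: np.ndarray, adjacency: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> np.ndarray:
    """Maximum-likelihood concentration matrix under zero constraints.

    ``K_ij = 0`` off-structure and ``(K^-1)_ij = S_ij`` on edges and the
    diagonal, computed by cyclic modified-regression updates (equivalent to
    iterative proportional fitting for this model class).
    """
    S = np.asarray(S, dtype=float)
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != S.shape or not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric and match S")
    if adjacency.diagonal().any():
        raise ValueError("adjacency diagonal must be empty (hollow matrix)")
    K, W, _, converged = ggm_refit(S, adjacency, tol, max_iter)
    if not converged:
        resid = float(np.max(np.abs(np.linalg.inv(K)[adjacency] - S[adjacency]))) if np.isfinite(K).all() else np.inf
        raise GgmConvergenceError(resid)
    return K


def gaussian_loglik(S: np.ndarray, K: np.ndarray, n: int) -> float:
    """Profile log-likelihood (n/2)(log det K - trace(S K)), constants dropped."""
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - float(np.sum(S * K)))


def ebic_score(loglik: float, n_edges: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC: -2*loglik + E*log n + 4*E*gamma*log p (lower is better)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)


def _score_structure(S, adj, n, gamma, tol, max_iter):
    K, _, _, converged = ggm_refit(S, adj, tol, max_iter)
    if not converged:
        raise GgmConvergenceError(np.nan)
    E = int(np.count_nonzero(np.triu(adj, 1)))
    return ebic_score(gaussian_loglik(S, K, n), E, n, S.shape[0], gamma), K


def ggm_model_select(
    S: np.ndarray,
    n: int,
    gamma: float = 0.5,
    labels: list[str] | None = None,
    n_penalties: int = 100,
    min_penalty_frac: float = 0.01,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> PartialCorrelationNetwork:
    """EBIC model selection over unregularized GGM refits.

    ``S`` must be a positive-definite correlation matrix (data are assumed
    gaussianized to unit variance upstream, so correlation and covariance
    coincide).  Deterministic given ``S``: the penalty path is a fixed
    log-spaced grid and the stepwise search is steepest-descent.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if labels is None:
        labels = [f"V{i + 1}" for i in range(p)]
    if np.linalg.eigvalsh(S)[0] <= 0:
        raise ValueError("S must be positive definite")

    offmax = float(np.max(np.abs(S - np.diag(np.diag(S))))) if p > 1 else 0.0
    candidates: dict[bytes, np.ndarray] = {}
    empty = np.zeros((p, p), dtype=bool)
    candidates[empty.tobytes()] = empty
    if offmax > 0:
        for alpha in np.geomspace(offmax, offmax * min_penalty_frac, n_penalties):
            pat = np.asarray(glasso_pattern(S, float(alpha)), dtype=bool)
            candidates[pat.tobytes()] = pat

    best_score, best_adj, best_K = np.inf, empty, None
    for adj in candidates.values():
        score, K = _score_structure(S, adj, n, gamma, tol, max_iter)
        if score < best_score:
            best_score, best_adj, best_K = score, adj, K

    trace = [best_score]
    iu = np.triu_indices(p, 1)
    while True:
        move_best, move_adj, move_K = best_score, None, None
        for i, j in zip(*iu):
            adj = best_adj.copy()
            adj[i, j] = adj[j, i] = not adj[i, j]
            try:
                score, K = _score_structure(S, adj, n, gamma, tol, max_iter)
            except GgmConvergenceError:
                continue
            if score < move_best:
                move_best, move_adj, move_K = score, adj, K
        if move_adj is None:
            break
        best_score, best_adj, best_K = move_best, move_adj, move_K
        trace.append(best_score)

    d = np.sqrt(np.diag(best_K))
    weights = -best_K / np.outer(d, d)
    np.fill_diagonal(weights, 0.0)
    weights[~best_adj] = 0.0
    return PartialCorrelationNetwork(list(labels), weights, best_K, best_score, gamma, trace)


def centrality(net: PartialCorrelationNetwork) -> pd.DataFrame:
    """Strength, closeness and betweenness centrality of the network.

    Distances are 1/|weight| on edges; closeness is the reciprocal of the
    summed shortest-path distances to the node's component (0 for isolated
    nodes); betweenness counts node appearances on all-pairs shortest paths
    with ties split equally.  A ``connected`` flag marks whether closeness
    was computed on the full graph or within a component.
    """
    G = net.to_graph()
    strength = {v: 0.0 for v in net.labels}
    for u, v, d in G.edges(data=True):
        strength[u] += abs(d["weight"])
        strength[v] += abs(d["weight"])
    betw = nx.betweenness_centrality(G, weight="length", normalized=False) if G.number_of_edges() else dict.fromkeys(net.labels, 0.0)
    connected = nx.is_connected(G) if G.number_of_nodes() else False
    closeness = {}
    for v in net.labels:
        dists = nx.single_source_dijkstra_path_length(G, v, weight="length")
        total = sum(d for u, d in dists.items() if u != v)
        closeness[v] = 1.0 / total if total > 0 else 0.0
    return pd.DataFrame(
        {
            "strength": [strength[v] for v in net.labels],
            "closeness": [closeness[v] for v in net.labels],
            "betweenness": [betw[v] for v in net.labels],
            "connected_graph": connected,
        },
        index=net.labels,
    )
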