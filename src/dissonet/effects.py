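"""Posterior-averaged causal effects and the thresholded mixed graph.

Each sampled DAG is turned into a weighted linear SEM by least-squares
regression of every node on its parents (on gaussianized, unit-variance
data, so coefficients are standardized).  Summaries over the posterior
sample then follow the conventions of the source analysis:

* ``pathway_present_pct`` — % of all sampled DAGs containing a directed
  path source -> target;
* ``causal_effect`` with a 90% equal-tailed credible interval — mean total
  effect *conditional on the pathway being present*;
* ``direct_edge_pct`` — % of the *pathway-present* DAGs (not of all DAGs)
  that contain the direct edge;
* ``direct_causal_effect`` — mean direct-edge coefficient over DAGs
  containing that edge, with its own 90% interval;
* the mixed graph keeps an edge if it appears (in either orientation) in
  strictly more than 50% of sampled DAGs, and arrows it only if one
  orientation accounts for strictly more than 90% of those appearances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dag import WeightedDag, total_effect_matrix
from .dagmcmc import DagSampleSet

__all__ = [
    "EffectSummary",
    "MixedGraph",
    "fit_path_coefficients",
    "total_effect",
    "aggregate_effects",
    "effects_table",
    "mediator_share",
    "mixed_graph",
]


@dataclass
class EffectSummary:
    """One row of a posterior causal-effect table."""

    source: str
    target: str
    pathway_present_pct: float
    causal_effect: float | None
    ci90: tuple[float, float] | None
    direct_edge_pct: float | None
    direct_causal_effect: float | None
    direct_ci90: tuple[float, float] | None

    def as_row(self) -> dict:
        lo, hi = self.ci90 if self.ci90 else (np.nan, np.nan)
        dlo, dhi = self.direct_ci90 if self.direct_ci90 else (np.nan, np.nan)
        return {
            "source": self.source,
            "target": self.target,
            "pathway_present_pct": self.pathway_present_pct,
            "causal_effect": np.nan if self.causal_effect is None else self.causal_effect,
            "ci90_lo": lo,
            "ci90_hi": hi,
            "direct_edge_pct": np.nan if self.direct_edge_pct is None else self.direct_edge_pct,
            "direct_causal_effect": np.nan
            if self.direct_causal_effect is None
            else self.direct_causal_effect,
            "direct_ci90_lo": dlo,
            "direct_ci90_hi": dhi,
        }


@dataclass
class MixedGraph:
    """Partially directed posterior summary graph."""

    nodes: list[str]
    undirected_edges: list[tuple[str, str]]
    directed_edges: list[tuple[str, str]]
    inclusion_freq: dict[tuple[str, str], float]
    direction_freq: dict[tuple[str, str], float]

    def to_graph(self) -> nx.DiGraph:
        """Directed edges as arcs; undirected edges as reciprocal arc pairs
        flagged ``directed=False`` (GraphML-friendly encoding)."""
        G = nx.DiGraph()
        G.add_nodes_from(self.nodes)
        for u, v in self.directed_edges:
            key = (u, v) if (u, v) in self.inclusion_freq else (v, u)
            G.add_edge(u, v, directed=True, inclusion=self.inclusion_freq[key],
                       direction=self.direction_freq.get((u, v), np.nan))
        for u, v in self.undirected_edges:
            key = (u, v) if (u, v) in self.inclusion_freq else (v, u)
            for a, b in ((u, v), (v, u)):
                G.add_edge(a, b, directed=False, inclusion=self.inclusion_freq[key],
                           direction=np.nan)
        return G


def _coefficients_for_masks(parent_masks: tuple[int, ...], S: np.ndarray) -> np.ndarray:
    """Per-node least-squares path coefficients from a covariance matrix."""
    p = len(parent_masks)
    W = np.zeros((p, p))
    for v, m in enumerate(parent_masks):
        if m == 0:
            continue
        pa = [i for i in range(p) if m >> i & 1]
        A = S[np.ix_(pa, pa)]
        b = S[pa, v]
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            warnings.warn(f"collinear parents for node {v}; minimum-norm solution", stacklevel=2)
            beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        W[pa, v] = beta
    return W


def fit_path_coefficients(dag: WeightedDag | tuple[int, ...], z, labels=None) -> WeightedDag:
    """Fit standardized path coefficients of ``dag`` on data ``z`` by OLS.

    ``dag`` may be a :class:`WeightedDag` (weights are refit) or a tuple of
    parent bitmasks with ``labels``.  Returns a new :class:`WeightedDag`.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    S = z.T @ z / n
    if isinstance(dag, WeightedDag):
        labels = dag.nodes
        idx = dag.index()
        masks = [0] * dag.p
        for u, v in dag.edges:
            masks[idx[v]] |= 1 << idx[u]
        masks = tuple(masks)
    else:
        if labels is None:
            raise ValueError("labels required with bitmask input")
        masks = tuple(dag)
    W = _coefficients_for_masks(masks, S)
    edges, weights = [], {}
    for v, m in enumerate(masks):
        for u in range(len(masks)):
            if m >> u & 1:
                edges.append((labels[u], labels[v]))
                weights[(labels[u], labels[v])] = float(W[u, v])
    return WeightedDag(list(labels), edges, weights)


def total_effect(weighted: WeightedDag, source: str, target: str) -> float:
    """Total causal effect: the (source, target) entry of (I - W)^-1 - I,
    equal to the sum over directed paths of coefficient products."""
    if source == target:
        raise ValueError("source and target must differ")
    idx = weighted.index()
    if source not in idx or target not in idx:
        raise KeyError(f"unknown node in ({source}, {target})")
    T = total_effect_matrix(weighted.weight_matrix())
    return float(T[idx[source], idx[target]])


class _SampleCache:
    """Per-unique-structure fitted coefficients, reachability and effects."""

    def __init__(self, samples: DagSampleSet, z: np.ndarray):
        z = np.asarray(z, dtype=float)
        if z.shape[1] != samples.p:
            raise ValueError("z columns do not match sampled variables")
        self.labels = samples.labels
        self.p = samples.p
        S = z.T @ z / z.shape[0]
        self.structures = []  # (count, W, reach, T)
        self.total = len(samples)
        for masks, count in samples.unique_dags().items():
            W = _coefficients_for_masks(masks, S)
            A = W != 0.0
            for v, m in enumerate(masks):  # keep explicit zeros as edges
                for u in range(self.p):
                    if m >> u & 1:
                        A[u, v] = True
            reach = _reachability(A)
            T = total_effect_matrix(W)
            self.structures.append((count, masks, W, reach, T))


def _reachability(A: np.ndarray) -> np.ndarray:
    """Boolean transitive closure of adjacency A (excluding trivial self-paths)."""
    p = A.shape[0]
    R = A.copy()
    for k in range(p):
        R |= np.outer(R[:, k], R[k, :])
    return R


def _pct_interval(values: np.ndarray, counts: np.ndarray) -> tuple[float, tuple[float, float]]:
    expanded = np.repeat(values, counts)
    return float(expanded.mean()), (
        float(np.percentile(expanded, 5)),
        float(np.percentile(expanded, 95)),
    )


def aggregate_effects(samples: DagSampleSet, z, source: str, target: str,
                      _cache: "_SampleCache | None" = None) -> EffectSummary:
    """Posterior summary of the causal pathway source -> target (one table row)."""
    cache = _cache or _SampleCache(samples, z)
    idx = {v: i for i, v in enumerate(cache.labels)}
    s, t = idx[source], idx[target]
    if s == t:
        raise ValueError("source and target must differ")
    pres_vals, pres_counts = [], []
    direct_count = 0
    direct_vals, direct_counts = [], []
    present = 0
    for count, masks, W, reach, T in cache.structures:
        if reach[s, t]:
            present += count
            pres_vals.append(T[s, t])
            pres_counts.append(count)
            if masks[t] >> s & 1:
                direct_count += count
                direct_vals.append(W[s, t])
                direct_counts.append(count)
    pct = 100.0 * present / cache.total
    if present == 0:
        return EffectSummary(source, target, 0.0, None, None, None, None, None)
    eff, ci = _pct_interval(np.array(pres_vals), np.array(pres_counts))
    direct_pct = 100.0 * direct_count / present
    if direct_count:
        deff, dci = _pct_interval(np.array(direct_vals), np.array(direct_counts))
    else:
        deff, dci = None, None
    return EffectSummary(source, target, pct, eff, ci, direct_pct, deff, dci)


def effects_table(samples: DagSampleSet, z, focus: str,
                  others: list[str] | None = None) -> pd.DataFrame:
    """Both-direction effect summaries between ``focus`` and every other node
    (the shape of the published per-construct causal-effect tables)."""
    cache = _SampleCache(samples, np.asarray(z, dtype=float))
    others = others or [v for v in samples.labels if v != focus]
    rows = []
    for other in others:
        rows.append(aggregate_effects(samples, z, other, focus, _cache=cache).as_row())
    for other in others:
        rows.append(aggregate_effects(samples, z, focus, other, _cache=cache).as_row())
    return pd.DataFrame(rows)


def mediator_share(samples: DagSampleSet, z, source: str, target: str, via: str,
                   _cache: "_SampleCache | None" = None) -> float:
    """Among pathway-present DAGs, the % in which at least one directed path
    source -> target passes through ``via``.  (In a DAG, reachability
    source -> via and via -> target implies such a path.)"""
    if via in (source, target):
        raise ValueError("mediator must differ from source and target")
    cache = _cache or _SampleCache(samples, z)
    idx = {v: i for i, v in enumerate(cache.labels)}
    s, t, m = idx[source], idx[target], idx[via]
    present = 0
    through = 0
    for count, masks, W, reach, T in cache.structures:
        if reach[s, t]:
            present += count
            if reach[s, m] and reach[m, t]:
                through += count
    if present == 0:
        return 0.0
    return 100.0 * through / present


def mixed_graph(samples: DagSampleSet, edge_threshold: float = 0.50,
                direction_threshold: float = 0.90) -> MixedGraph:
    """Posterior summary graph with strict inclusion/orientation thresholds."""
    if not 0 < edge_threshold <= 1 or not 0 < direction_threshold <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    p = samples.p
    F = samples.edge_frequency_matrix() * len(samples)  # counts u->v
    labels = samples.labels
    undirected, directed = [], []
    incl, direc = {}, {}
    total = len(samples)
    for i in range(p):
        for j in range(i + 1, p):
            both = F[i, j] + F[j, i]
            freq = both / total
            if freq <= edge_threshold:
                continue
            incl[(labels[i], labels[j])] = freq
            share_ij = F[i, j] / both
            if share_ij > direction_threshold:
                directed.append((labels[i], labels[j]))
                direc[(labels[i], labels[j])] = share_ij
            elif 1.0 - share_ij > direction_threshold:
                directed.append((labels[j], labels[i]))
                direc[(labels[j], labels[i])] = 1.0 - share_ij
            else:
                undirected.append((labels[i], labels[j]))
    return MixedGraph(list(labels), undirected, directed, incl, direc)
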