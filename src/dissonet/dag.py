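"""Weighted directed acyclic graphs with linear path coefficients.

A :class:`WeightedDag` is both the ground truth of the synthetic generator
(a linear-Gaussian structural equation model) and the fitted object attached
to each posterior DAG sample.  Edge weight ``w`` on ``u -> v`` is the
standardized path coefficient of ``u`` in the structural equation of ``v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CyclicGraphError(ValueError):
    """Raised when an edge set admits no topological order."""


@dataclass
class WeightedDag:
    nodes: list[str]
    edges: list[tuple[str, str]]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node labels")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u}->{v}")
            if u not in node_set or v not in node_set:
                raise KeyError(f"edge {u}->{v} references unknown node")
        for key in self.weights:
            if key not in set(self.edges):
                raise ValueError(f"weight for non-edge {key}")
        if not self.noise_sd:
            self.noise_sd = {v: 1.0 for v in self.nodes}
        for v, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise_sd[{v}] must be strictly positive")
        self.topological_order()  # raises CyclicGraphError on a cycle

    @property
    def p(self) -> int:
        return len(self.nodes)

    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.nodes)}

    def parents(self, v: str) -> list[str]:
        return [u for u, w in self.edges if w == v]

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; raises :class:`CyclicGraphError` on a cycle."""
        indeg = {v: 0 for v in self.nodes}
        children: dict[str, list[str]] = {v: [] for v in self.nodes}
        for u, v in self.edges:
            indeg[v] += 1
            children[u].append(v)
        ready = [v for v in self.nodes if indeg[v] == 0]
        order: list[str] = []
        while ready:
            v = ready.pop()
            order.append(v)
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self.nodes):
            raise CyclicGraphError("edge set contains a directed cycle")
        return order

    def weight_matrix(self) -> np.ndarray:
        """W with W[i, j] = coefficient of nodes[i] in the equation of nodes[j]."""
        idx = self.index()
        W = np.zeros((self.p, self.p))
        for (u, v), w in self.weights.items():
            W[idx[u], idx[v]] = w
        return W

    def adjacency(self) -> np.ndarray:
        idx = self.index()
        A = np.zeros((self.p, self.p), dtype=bool)
        for u, v in self.edges:
            A[idx[u], idx[v]] = True
        return A


def total_effect_matrix(W: np.ndarray) -> np.ndarray:
    """Total causal effects of a linear SEM: (I - W)^-1 - I.

    Entry [i, j] is the sum over all directed paths i -> ... -> j of the
    products of path coefficients (W as in :meth:`WeightedDag.weight_matrix`).
    """
    p = W.shape[0]
    return np.linalg.inv(np.eye(p) - W) - np.eye(p)


def enumerate_path_effects(dag: WeightedDag, source: str, target: str) -> float:
    """Total effect by exhaustive directed-path enumeration (oracle).

    Exponential in the worst case; intended for small graphs and testing the
    matrix identity, not for production use.
    """
    children: dict[str, list[str]] = {v: [] for v in dag.nodes}
    for u, v in dag.edges:
        children[u].append(v)

    total = 0.0

    def walk(node: str, product: float) -> None:
        nonlocal total
        if node == target:
            total += product
            return
        for c in children[node]:
            walk(c, product * dag.weights.get((node, c), 0.0))

    if source == target:
        return 0.0
    for c in children[source]:
        walk(c, dag.weights.get((source, c), 0.0))
    return total
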