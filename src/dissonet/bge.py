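"""Bayesian Gaussian-equivalent (BGe) local scores for DAG structure learning.

The marginal likelihood of Gaussian data given a DAG under a conjugate
normal-Wishart prior decomposes into per-node terms ("local scores") that
depend only on the node and its parent set.  Markov-equivalent DAGs receive
identical total scores (score equivalence), which the test suite checks by
covered-edge reversals.

Parent sets are encoded as integer bitmasks over the node order of the data
columns; local scores and the sub-determinants they need are memoized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ScoreConfig", "BgeScore"]


@dataclass(frozen=True)
class ScoreConfig:
    """Hyperparameters of the BGe score.

    ``am`` is the prior precision on the mean (alpha_mu); ``aw`` the
    Wishart degrees of freedom (alpha_w, default p+2 — weakly informative);
    ``edge_penalty`` is a per-parent log-prior increment added to each local
    score (0 = uniform structure prior; negative values penalize edges while
    keeping the prior modular, so every sampler and oracle in this package
    stays exact under it).
    """

    am: float = 1.0
    aw: float | None = None
    edge_penalty: float = 0.0

    def resolve_aw(self, p: int) -> float:
        aw = self.aw if self.aw is not None else p + 2.0
        if aw <= p + 1:
            raise ValueError(f"aw must exceed p+1={p + 1}")
        return aw


class BgeScore:
    """Memoized BGe local scores for one dataset.

    Parameters
    ----------
    data:
        n x p matrix; columns are the network variables.  Internally only the
        centered scatter matrix and n are used, so gaussianized scale scores
        and pooled correlation matrices (times n) are equally valid inputs
        via ``from_scatter``.
    """

    def __init__(self, data: np.ndarray, config: ScoreConfig | None = None,
                 labels: list[str] | None = None):
        data = np.asarray(data, dtype=float)
        n, p = data.shape
        xbar = data.mean(axis=0)
        scatter = (data - xbar).T @ (data - xbar)
        self._init(scatter, n, p, config, labels)

    @classmethod
    def from_scatter(cls, scatter: np.ndarray, n: int, config: ScoreConfig | None = None,
                     labels: list[str] | None = None) -> "BgeScore":
        self = cls.__new__(cls)
        self._init(np.asarray(scatter, dtype=float), n, scatter.shape[0], config, labels)
        return self

    def _init(self, scatter, n, p, config, labels):
        self.config = config or ScoreConfig()
        if self.config.am <= 0:
            raise ValueError("am must be positive")
        self.n = int(n)
        self.p = int(p)
        self.labels = labels or [f"V{i + 1}" for i in range(p)]
        am = self.config.am
        aw = self.config.resolve_aw(p)
        self.aw = aw
        # prior scatter T = t * I with the standard scale making the score
        # equivalent across Markov-equivalent DAGs
        self.t = am * (aw - p - 1.0) / (am + 1.0)
        self.R = self.t * np.eye(p) + scatter
        self._logdet_cache: dict[int, float] = {0: 0.0}
        self._score_cache: dict[tuple[int, int], float] = {}
        # per-parent-set-size constants
        N = self.n
        self._const = {}
        for l in range(p):
            self._const[l] = (
                0.5 * (math.log(am) - math.log(am + N))
                - 0.5 * N * math.log(math.pi)
                + math.lgamma(0.5 * (N + aw - p + l + 1))
                - math.lgamma(0.5 * (aw - p + l + 1))
                + 0.5 * (aw - p + 2 * l + 1) * math.log(self.t)
            )

    def _logdet(self, mask: int) -> float:
        got = self._logdet_cache.get(mask)
        if got is not None:
            return got
        idx = [i for i in range(self.p) if mask >> i & 1]
        sign, ld = np.linalg.slogdet(self.R[np.ix_(idx, idx)])
        if sign <= 0:
            raise np.linalg.LinAlgError("posterior scatter submatrix not positive definite")
        self._logdet_cache[mask] = ld
        return ld

    def local_score(self, node: int, parent_mask: int) -> float:
        """Log marginal-likelihood contribution of ``node`` given its parents."""
        if parent_mask >> node & 1:
            raise ValueError("parent set must exclude the node itself")
        key = (node, parent_mask)
        got = self._score_cache.get(key)
        if got is not None:
            return got
        l = int(parent_mask).bit_count()
        N, aw, p = self.n, self.aw, self.p
        fam = parent_mask | (1 << node)
        score = (
            self._const[l]
            + 0.5 * (N + aw - p + l) * self._logdet(parent_mask)
            - 0.5 * (N + aw - p + l + 1) * self._logdet(fam)
            + self.config.edge_penalty * l
        )
        self._score_cache[key] = score
        return score

    def dag_score(self, parent_masks: tuple[int, ...]) -> float:
        """Total log score of a DAG given as per-node parent bitmasks."""
        return sum(self.local_score(j, m) for j, m in enumerate(parent_masks))

    def all_local_scores(self) -> np.ndarray:
        """Dense (p, 2^p) table of local scores; entries whose mask contains
        the node are -inf.  Feasible for p <= ~16."""
        if self.p > 16:
            raise ValueError("dense score table infeasible beyond p=16")
        table = np.full((self.p, 1 << self.p), -np.inf)
        for j in range(self.p):
            rest = [i for i in range(self.p) if i != j]
            for sub in range(1 << (self.p - 1)):
                mask = 0
                s = sub
                for i in rest:
                    if s & 1:
                        mask |= 1 << i
                    s >>= 1
                table[j, mask] = self.local_score(j, mask)
        return table
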