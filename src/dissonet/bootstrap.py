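"""Bootstrap accuracy and stability of the partial-correlation network.

Implements the standard accuracy/stability battery for psychological
networks: nonparametric bootstrap of edge weights (with quantile CIs and
edge-inclusion frequencies), bootstrapped edge-difference tests, and
case-dropping subsample bootstraps summarized by correlation-stability
(CS) coefficients for the centrality indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .ggm import PartialCorrelationNetwork, centrality, ggm_model_select

__all__ = ["BootResult", "nonparametric_boot", "edge_difference_test", "case_drop_boot"]

DROP_FRACS = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))


@dataclass
class BootResult:
    """Edge-weight bootstrap output.

    ``edge_draws`` is B x p(p-1)/2 (upper-triangular order, absent edges as
    exact 0); ``ci`` holds the per-edge [2.5%, 97.5%] quantiles.
    """

    labels: list[str]
    point: PartialCorrelationNetwork
    edge_draws: np.ndarray
    ci: np.ndarray  # (n_edges, 2)
    inclusion_freq: np.ndarray
    n_failed: int = 0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def edge_names(self) -> list[tuple[str, str]]:
        p = len(self.labels)
        return [(self.labels[i], self.labels[j]) for i in range(p) for j in range(i + 1, p)]

    def edge_index(self, edge: tuple[str, str]) -> int:
        names = self.edge_names
        if edge in names:
            return names.index(edge)
        if (edge[1], edge[0]) in names:
            return names.index((edge[1], edge[0]))
        raise KeyError(f"unknown edge {edge}")

    def summary(self) -> pd.DataFrame:
        est = self.point.edge_vector()
        return pd.DataFrame(
            {
                "node1": [a for a, _ in self.edge_names],
                "node2": [b for _, b in self.edge_names],
                "estimate": est,
                "ci_lo": self.ci[:, 0],
                "ci_hi": self.ci[:, 1],
                "inclusion_freq": self.inclusion_freq,
            }
        )

    def difference_matrix(self) -> np.ndarray:
        """Symmetric boolean matrix of pairwise edge-difference significance."""
        m = self.edge_draws.shape[1]
        out = np.zeros((m, m), dtype=bool)
        for a in range(m):
            for b in range(a + 1, m):
                out[a, b] = out[b, a] = _interval_excludes_zero(
                    self.edge_draws[:, a] - self.edge_draws[:, b]
                )
        return out


def _interval_excludes_zero(diff: np.ndarray) -> bool:
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return bool(lo > 0 or hi < 0)


def _resample_indices(seed, B, n) -> np.ndarray:
    """Replicate indices depend only on (seed, B, n) — estimator-agnostic."""
    return np.random.default_rng(seed).integers(0, n, size=(B, n))


def nonparametric_boot(
    z: np.ndarray,
    B: int = 5000,
    seed: int | None = None,
    gamma: float = 0.5,
    labels: list[str] | None = None,
    max_failure_frac: float = 0.01,
    **select_kwargs,
) -> BootResult:
    """Row-resampling bootstrap of the whole model-selection procedure.

    Each replicate re-estimates the network with identical settings on n
    rows drawn with replacement; failed refits are dropped (aborting if
    more than ``max_failure_frac`` of replicates fail).
    """
    if B < 100:
        raise ValueError("B must be >= 100 for quantile CIs")
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    point = ggm_model_select(np.corrcoef(z.T), n, gamma=gamma, labels=labels, **select_kwargs)
    idx = _resample_indices(seed, B, n)
    draws = np.zeros((B, p * (p - 1) // 2))
    failed = 0
    kept = []
    for b in range(B):
        zb = z[idx[b]]
        Sb = np.corrcoef(zb.T)
        try:
            net = ggm_model_select(Sb, n, gamma=gamma, **select_kwargs)
        except (ValueError, np.linalg.LinAlgError, RuntimeError):
            failed += 1
            if failed > max_failure_frac * B:
                raise RuntimeError(f"more than {max_failure_frac:.0%} of replicates failed")
            continue
        draws[b] = net.edge_vector()
        kept.append(b)
    draws = draws[kept]
    ci = np.percentile(draws, [2.5, 97.5], axis=0).T
    incl = (draws != 0).mean(axis=0)
    return BootResult(point.labels, point, draws, ci, incl, failed, seed,
                      {"B": B, "gamma": gamma})


def edge_difference_test(result: BootResult, edge_a, edge_b) -> bool:
    """True when the 95% bootstrap interval of (w_a - w_b) excludes zero."""
    ia, ib = result.edge_index(tuple(edge_a)), result.edge_index(tuple(edge_b))
    if ia == ib:
        return False
    return _interval_excludes_zero(result.edge_draws[:, ia] - result.edge_draws[:, ib])


def case_drop_boot(
    z: np.ndarray,
    drop_fracs: tuple[float, ...] = DROP_FRACS,
    B: int = 250,
    seed: int | None = None,
    gamma: float = 0.5,
    labels: list[str] | None = None,
    corr_threshold: float = 0.7,
    prop_threshold: float = 0.95,
    **select_kwargs,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Case-dropping bootstrap of centrality stability.

    Returns (CS coefficients per centrality index, long table of per-level
    correlation summaries).  CS is the largest drop fraction at which the
    Spearman correlation between subsample and full-sample centralities is
    at least ``corr_threshold`` in at least ``prop_threshold`` of replicates.
    """
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    full = centrality(ggm_model_select(np.corrcoef(z.T), n, gamma=gamma, labels=labels,
                                       **select_kwargs))
    kinds = ["strength", "closeness", "betweenness"]
    rng = np.random.default_rng(seed)
    rows = []
    ok_prop: dict[str, dict[float, float]] = {k: {} for k in kinds}
    for frac in drop_fracs:
        keep = int(round(n * (1 - frac)))
        if keep < 50:
            raise ValueError(f"drop fraction {frac} leaves fewer than 50 rows")
        ok = {k: 0 for k in kinds}
        for _ in range(B):
            sub = rng.choice(n, size=keep, replace=False)
            zb = z[sub]
            try:
                cent = centrality(ggm_model_select(np.corrcoef(zb.T), keep, gamma=gamma,
                                                   labels=full.index.tolist(), **select_kwargs))
            except (ValueError, np.linalg.LinAlgError, RuntimeError):
                continue
            for k in kinds:
                r = spearmanr(full[k], cent[k]).statistic
                if np.isnan(r):
                    r = 0.0
                if r >= corr_threshold:
                    ok[k] += 1
        for k in kinds:
            prop = ok[k] / B
            ok_prop[k][frac] = prop
            rows.append({"drop_frac": frac, "centrality": k, "prop_stable": prop})
    cs = {}
    for k in kinds:
        passing = [f for f in drop_fracs if ok_prop[k][f] >= prop_threshold]
        cs[k] = max(passing) if passing else 0.0
    return cs, pd.DataFrame(rows)
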