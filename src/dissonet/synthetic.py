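"""Synthetic Likert-questionnaire studies with known causal ground truth.

The generator emulates the structure of a large online survey: ``n``
respondents answer a battery of multi-item Likert scales whose construct-level
scores follow a known sparse linear-Gaussian DAG.  Every downstream stage of
the pipeline (scoring, gaussianization, GGM selection, DAG posterior
averaging, causal-effect summaries) can then be validated by parameter
recovery against this ground truth.

Construct scores are generated in topological order from

    X_j = sum_{k in pa(j)} w_kj X_k + eps_j,   eps_j ~ N(0, sd_j^2)

so the population covariance is ``(I - W)^-T D (I - W)^-1`` (with W the
upper-triangular coefficient matrix in topological order and D the diagonal
of noise variances).  Items are one-factor congeneric indicators of the
standardized construct score, discretized at equiprobable normal thresholds;
missingness is MCAR.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dag import WeightedDag, total_effect_matrix
from .scales import ScaleSpec, study_reliabilities, study_scales

__all__ = [
    "LikertDataset",
    "GeneratorConfig",
    "sample_random_dag",
    "sample_random_ggm",
    "simulate_construct_scores",
    "standardize_dag",
    "likertize",
    "inject_missingness",
    "true_total_effect",
    "default_study_dag",
    "demo_dag_small",
    "generate_study",
    "SyntheticStudy",
    "write_study",
    "read_study",
]


@dataclass
class LikertDataset:
    """Participant x item integer response table.

    ``items`` holds one column per item (``<scale>_<i>``), with ``NaN``
    marking missing responses; ``specs`` gives scale membership and
    reverse-coding flags.  Reverse-keyed items are stored already *flipped*
    (as a respondent would mark them), so scoring must un-flip them.
    """

    items: pd.DataFrame
    specs: list[ScaleSpec]

    def __post_init__(self) -> None:
        expected = [c for s in self.specs for c in s.item_columns()]
        missing = set(expected) - set(self.items.columns)
        if missing:
            raise ValueError(f"items table lacks columns {sorted(missing)[:5]}...")

    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.items.isna()

    def scale_columns(self, spec: ScaleSpec) -> pd.DataFrame:
        return self.items[spec.item_columns()]

    def copy(self) -> "LikertDataset":
        return LikertDataset(self.items.copy(), list(self.specs))


@dataclass
class GeneratorConfig:
    """Settings of one synthetic study.

    ``reliability`` maps scale name to the one-factor item loading
    lambda in (0, 1); ``missing_rate`` is the MCAR cell-missingness
    probability.  Defaults mirror the emulated survey: n = 6161
    respondents, loadings implied by the published alphas, 2% MCAR.
    """

    n: int = 6161
    seed: int = 0
    reliability: dict[str, float] = field(default_factory=study_reliabilities)
    missing_rate: float = 0.02
    mechanism: str = "MCAR"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for name, lam in self.reliability.items():
            if not 0 < lam < 1:
                raise ValueError(f"reliability[{name}] must be in (0, 1)")
        if self.mechanism != "MCAR":
            raise ValueError("only MCAR missingness is supported")


def sample_random_dag(
    p: int,
    edge_prob: float,
    weight_range: tuple[float, float] = (0.1, 0.6),
    seed: int | None = None,
    nodes: list[str] | None = None,
) -> WeightedDag:
    """Sample a random DAG over a random topological order.

    Each of the p(p-1)/2 ordered pairs becomes an edge with probability
    ``edge_prob``; weights are drawn uniformly from ``±[lo, hi]`` with
    ``lo >= 0.1`` required so that true edges remain detectable.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be in [0, 1]")
    lo, hi = weight_range
    if not 0.1 <= lo <= hi:
        raise ValueError("weight_range must satisfy 0.1 <= lo <= hi (band excluding 0)")
    rng = np.random.default_rng(seed)
    if nodes is None:
        nodes = [f"X{i}" for i in range(1, p + 1)]
    elif len(nodes) != p:
        raise ValueError("len(nodes) != p")
    order = rng.permutation(p)
    edges: list[tuple[str, str]] = []
    weights: dict[tuple[str, str], float] = {}
    for a in range(p):
        for b in range(a + 1, p):
            if rng.random() < edge_prob:
                u, v = nodes[order[a]], nodes[order[b]]
                w = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                edges.append((u, v))
                weights[(u, v)] = w
    return WeightedDag(list(nodes), edges, weights, {v: 1.0 for v in nodes})


def sample_random_ggm(
    p: int,
    n_edges: int,
    min_abs_partial: float = 0.15,
    max_abs_partial: float = 0.4,
    seed: int | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """Sample a sparse positive-definite precision matrix with unit-diagonal
    rescaling, whose nonzero partial correlations all satisfy
    ``min_abs_partial <= |r| <= max_abs_partial``.

    Returns the p x p partial-correlation matrix R (zero diagonal); the
    implied correlation matrix is recoverable as the inverse of
    ``I - R`` renormalized, see :func:`ggm_correlation`.
    """
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    if n_edges > len(pairs):
        raise ValueError("n_edges exceeds the number of node pairs")
    for _ in range(max_tries):
        chosen = rng.choice(len(pairs), size=n_edges, replace=False)
        K = np.eye(p)
        for c in chosen:
            i, j = pairs[c]
            r = rng.uniform(min_abs_partial * 1.3, max_abs_partial) * rng.choice([-1.0, 1.0])
            K[i, j] = K[j, i] = -r
        # enforce positive definiteness by diagonal inflation, then renormalize
        ev = np.linalg.eigvalsh(K)
        if ev[0] < 0.05:
            K += (0.05 - ev[0]) * np.eye(p)
        d = np.sqrt(np.diag(K))
        K = K / np.outer(d, d)
        R = -K / np.sqrt(np.outer(np.diag(K), np.diag(K)))
        np.fill_diagonal(R, 0.0)
        off = R[np.triu_indices(p, 1)]
        nz = off[off != 0]
        if len(nz) == n_edges and np.min(np.abs(nz)) >= min_abs_partial:
            return R
    raise RuntimeError("could not generate a GGM with the requested partial-correlation band")


def ggm_correlation(partial: np.ndarray) -> np.ndarray:
    """Correlation matrix implied by a partial-correlation matrix."""
    p = partial.shape[0]
    K = np.eye(p) - partial  # unit-diagonal precision up to scaling
    Sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(Sigma))
    return Sigma / np.outer(d, d)


def simulate_construct_scores(dag: WeightedDag, n: int, seed: int | None = None) -> pd.DataFrame:
    """Draw n rows from the linear-Gaussian structural model of ``dag``."""
    rng = np.random.default_rng(seed)
    order = dag.topological_order()
    X = pd.DataFrame(np.zeros((n, dag.p)), columns=dag.nodes)
    for v in order:
        eps = rng.normal(0.0, dag.noise_sd[v], size=n)
        x = eps
        for u in dag.parents(v):
            x = x + dag.weights.get((u, v), 0.0) * X[u].to_numpy()
        X[v] = x
    return X


def population_covariance(dag: WeightedDag) -> np.ndarray:
    """Closed-form covariance (I-W)^-T D (I-W)^-1 of the structural model."""
    W = dag.weight_matrix()
    D = np.diag([dag.noise_sd[v] ** 2 for v in dag.nodes])
    M = np.linalg.inv(np.eye(dag.p) - W)
    return M.T @ D @ M


def standardize_dag(dag: WeightedDag) -> WeightedDag:
    """Rescale residual SDs so every node has unit marginal variance.

    With unit-variance nodes, path coefficients live on the standardized
    scale, so fitted standardized effects are directly comparable to the
    generator's ground-truth weights.  Raises if some node's parents already
    explain >= 1 unit of variance.
    """
    idx = dag.index()
    Sigma = np.zeros((dag.p, dag.p))
    noise_sd: dict[str, float] = {}
    for v in dag.topological_order():
        j = idx[v]
        pa = [idx[u] for u in dag.parents(v)]
        w = np.array([dag.weights[(dag.nodes[i], v)] for i in pa])
        if pa:
            Sigma[j, :] = w @ Sigma[np.ix_(pa, range(dag.p))]
            Sigma[:, j] = Sigma[j, :]
            explained = float(w @ Sigma[np.ix_(pa, pa)] @ w)
        else:
            explained = 0.0
        if explained >= 1.0:
            raise ValueError(f"parents of {v} explain {explained:.2f} >= 1 unit of variance")
        noise_sd[v] = float(np.sqrt(1.0 - explained))
        Sigma[j, j] = 1.0
    return WeightedDag(list(dag.nodes), list(dag.edges), dict(dag.weights), noise_sd)


def likertize(
    scores: pd.DataFrame,
    specs: list[ScaleSpec],
    reliability: dict[str, float] | float,
    seed: int | None = None,
) -> LikertDataset:
    """Emit congeneric Likert items for each construct score column.

    Each item's latent value is ``lambda * z + sqrt(1 - lambda^2) * noise``
    with ``z`` the standardized construct score, discretized into the item's
    categories at equiprobable standard-normal thresholds.  Reverse-keyed
    items are emitted flipped (``item_min + item_max - v``).
    """
    if len(specs) != scores.shape[1]:
        raise ValueError("need one ScaleSpec per score column")
    rng = np.random.default_rng(seed)
    n = len(scores)
    out: dict[str, np.ndarray] = {}
    for col, spec in zip(scores.columns, specs):
        lam = reliability[spec.name] if isinstance(reliability, dict) else float(reliability)
        if not 0 < lam < 1:
            raise ValueError(f"reliability for {spec.name} must be in (0, 1)")
        z = scores[col].to_numpy()
        z = (z - z.mean()) / z.std()
        cuts = norm.ppf(np.arange(1, spec.n_categories) / spec.n_categories)
        for i in range(1, spec.n_items + 1):
            latent = lam * z + np.sqrt(1 - lam**2) * rng.standard_normal(n)
            v = spec.item_min + np.searchsorted(cuts, latent, side="right").astype(np.int64)
            if i in spec.reverse_items:
                v = spec.item_min + spec.item_max - v
            out[f"{spec.name}_{i}"] = v
    items = pd.DataFrame(out, index=scores.index, dtype=float)
    return LikertDataset(items, list(specs))


def inject_missingness(data: LikertDataset, rate: float, seed: int | None = None) -> LikertDataset:
    """Mask each cell independently with probability ``rate`` (MCAR)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    out = data.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(out.items.shape) < rate
        vals = out.items.to_numpy(dtype=float)
        vals[mask] = np.nan
        out.items = pd.DataFrame(vals, index=out.items.index, columns=out.items.columns)
    return out


def true_total_effect(dag: WeightedDag, x: str, y: str) -> float:
    """Ground-truth total causal effect of ``x`` on ``y``: the sum over all
    directed paths of products of edge weights, i.e. entry (x, y) of
    ``(I - W)^-1 - I``."""
    idx = dag.index()
    if x not in idx or y not in idx:
        raise KeyError(f"unknown node in ({x}, {y})")
    T = total_effect_matrix(dag.weight_matrix())
    return float(T[idx[x], idx[y]])


def default_study_dag() -> WeightedDag:
    """A fixed sparse ground-truth DAG over the 12-construct battery.

    Hand-specified (not sampled) so that demo runs are stable across
    versions: appraisals and affect-sensitivity constructs feed
    dissociation, which in turn drives overwhelm beliefs, echoing the
    magnitude/sparsity regime of a real survey network.
    """
    edges_w = {
        ("ais", "asi"): 0.35,
        ("ais", "mes"): 0.40,
        ("asi", "bvs"): 0.45,
        ("asi", "cad"): 0.30,
        ("mes", "ptq"): 0.40,
        ("ptq", "cad"): 0.25,
        ("gse", "cad"): -0.25,
        ("gse", "ptq"): -0.30,
        ("oaq", "dissociation"): 0.20,
        ("cad", "dissociation"): 0.55,
        ("ptq", "dissociation"): 0.15,
        ("dissociation", "rtd"): 0.50,
        ("dissociation", "ovw"): 0.35,
        ("atc", "ptq"): -0.20,
        ("oaq", "mes"): 0.25,
    }
    nodes = [s.name for s in study_scales()]
    return WeightedDag(nodes, list(edges_w), dict(edges_w))


def demo_dag_small() -> WeightedDag:
    """A 6-construct sub-study used by the fast demo/test profile."""
    edges_w = {
        ("gse", "cad"): -0.30,
        ("gse", "ptq"): -0.35,
        ("mes", "ptq"): 0.40,
        ("ptq", "cad"): 0.30,
        ("cad", "dissociation"): 0.55,
        ("ptq", "dissociation"): 0.20,
        ("dissociation", "ovw"): 0.40,
    }
    nodes = ["dissociation", "cad", "gse", "mes", "ptq", "ovw"]
    return WeightedDag(nodes, list(edges_w), dict(edges_w))


@dataclass
class SyntheticStudy:
    """One generated study: ground truth plus everything a user would see."""

    config: GeneratorConfig
    dag: WeightedDag
    scores: pd.DataFrame
    data: LikertDataset
    ages: pd.Series


def generate_study(
    config: GeneratorConfig | None = None,
    dag: WeightedDag | None = None,
) -> SyntheticStudy:
    """Generate a complete synthetic study from a ground-truth DAG.

    Ages are drawn from a normal distribution matched to the emulated
    survey (mean 45.6, SD 14.7, floored at 18) so the age-outlier
    exclusion rule has work to do.
    """
    cfg = config or GeneratorConfig()
    dag = dag or default_study_dag()
    rng = np.random.default_rng(cfg.seed)
    s_scores, s_items, s_miss, s_age = rng.integers(0, 2**31, size=4)
    by_name = {s.name: s for s in study_scales()}
    unknown = set(dag.nodes) - set(by_name)
    if unknown:
        raise ValueError(
            f"dag nodes {sorted(unknown)} are not battery scales; use likertize directly"
        )
    specs = [by_name[v] for v in dag.nodes]
    scores = simulate_construct_scores(dag, cfg.n, seed=int(s_scores))
    data = likertize(scores, specs, cfg.reliability, seed=int(s_items))
    data = inject_missingness(data, cfg.missing_rate, seed=int(s_miss))
    ages = pd.Series(
        np.maximum(18, np.round(rng.normal(45.6, 14.7, size=cfg.n))).astype(int),
        index=data.items.index,
        name="age",
    )
    return SyntheticStudy(cfg, dag, scores, data, ages)


# ---------------------------------------------------------------------------
# plain-text persistence: items CSV + YAML-style sidecar with specs and truth


def write_study(study: SyntheticStudy, data_path, sidecar_path) -> None:
    df = study.data.items.copy()
    df.insert(0, "participant_id", df.index)
    df.insert(1, "age", study.ages.to_numpy())
    df.to_csv(data_path, index=False)
    buf = io.StringIO()
    buf.write(f"n: {study.config.n}\nseed: {study.config.seed}\n")
    buf.write(f"missing_rate: {study.config.missing_rate}\nmechanism: {study.config.mechanism}\n")
    buf.write("scales:\n")
    for s in study.data.specs:
        rev = ",".join(str(i) for i in sorted(s.reverse_items))
        buf.write(
            f"  - name: {s.name}\n    n_items: {s.n_items}\n"
            f"    item_min: {s.item_min}\n    item_max: {s.item_max}\n"
            f"    reverse_items: \"{rev}\"\n"
            f"    reliability: {study.config.reliability[s.name]:.6f}\n"
        )
    buf.write("true_dag:\n")
    for u, v in study.dag.edges:
        buf.write(f"  - \"{u},{v},{study.dag.weights[(u, v)]:.6f}\"\n")
    with open(sidecar_path, "w") as fh:
        fh.write(buf.getvalue())


def read_study(data_path, sidecar_path) -> tuple[LikertDataset, pd.Series, WeightedDag, dict[str, float]]:
    """Read back the CSV + sidecar written by :func:`write_study`."""
    import yaml

    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    specs = []
    reliability = {}
    for entry in meta["scales"]:
        rev = frozenset(int(i) for i in str(entry["reverse_items"]).split(",") if i != "")
        specs.append(
            ScaleSpec(entry["name"], int(entry["n_items"]), int(entry["item_min"]), int(entry["item_max"]), rev)
        )
        reliability[entry["name"]] = float(entry["reliability"])
    df = pd.read_csv(data_path)
    df = df.set_index("participant_id")
    ages = df.pop("age")
    nodes = [s.name for s in specs]
    edges, weights = [], {}
    for line in meta.get("true_dag", []):
        u, v, w = line.split(",")
        edges.append((u, v))
        weights[(u, v)] = float(w)
    dag = WeightedDag(nodes, edges, weights)
    return LikertDataset(df, specs), ages, dag, reliability
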