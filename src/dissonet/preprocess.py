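"""Participant exclusions, imputation, scale scoring and gaussianization.

The cleaning pipeline mirrors a common survey-analysis protocol:

1. exclude respondents below the age-inclusion floor, those missing more
   than 20% of the items of *any* single measure, and age outliers more
   than two standard deviations above the sample mean age;
2. multiply impute remaining item-level missingness by chained equations
   with predictive mean matching;
3. score scales (un-flipping reverse-keyed items) and compute Cronbach's
   alpha per scale;
4. map each scale total through a rank-based inverse-normal transform so
   the network stages see (marginally) Gaussian variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .scales import ScaleSpec
from .synthetic import LikertDataset

__all__ = [
    "CleanDataset",
    "EmptyCohortError",
    "filter_participants",
    "impute",
    "score_scales",
    "cronbach_alpha",
    "gaussianize",
    "preprocess_study",
]


class EmptyCohortError(RuntimeError):
    """All participants were excluded."""


@dataclass
class CleanDataset:
    """Post-preprocessing construct-level data.

    ``totals`` are integer scale scores; ``z`` the gaussianized versions
    (exact mean 0, SD 1 per column).  Rows of both align with ``kept_ids``.
    """

    totals: pd.DataFrame
    z: pd.DataFrame
    kept_ids: list
    exclusion_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reason"])
    )


def filter_participants(
    data: LikertDataset,
    ages: pd.Series,
    max_missing_frac: float = 0.20,
    age_sd_mult: float = 2.0,
    min_age: int = 18,
    age_cutoff: float | None = None,
) -> tuple[LikertDataset, pd.Series, pd.DataFrame]:
    """Apply the exclusion rules; returns (kept data, kept ages, log).

    Reasons are assigned in a fixed priority order, one per excluded row:
    ``age_ineligible`` (below the inclusion floor), then ``missingness``
    (more than ``max_missing_frac`` of the items of any single scale
    missing, strictly), then ``age_outlier`` (strictly above mean +
    ``age_sd_mult`` * SD, with mean/SD computed over age-eligible rows).

    The applied upper age cutoff is recorded in ``log.attrs["age_cutoff"]``;
    passing it back via ``age_cutoff`` makes the filter idempotent (a
    recomputed mean + 2 SD bound on an already-truncated sample would keep
    shaving the upper tail).
    """
    if len(ages) != data.n:
        raise ValueError("ages not aligned with data rows")
    ages = pd.Series(np.asarray(ages, dtype=float), index=data.items.index)
    reasons: dict = {}

    eligible = ages >= min_age
    for pid in data.items.index[~eligible]:
        reasons[pid] = "age_ineligible"

    mask = data.mask
    too_missing = pd.Series(False, index=data.items.index)
    for spec in data.specs:
        frac = mask[spec.item_columns()].mean(axis=1)
        too_missing |= frac > max_missing_frac
    for pid in data.items.index[eligible & too_missing]:
        reasons[pid] = "missingness"

    if age_cutoff is None:
        mean, sd = ages[eligible].mean(), ages[eligible].std()
        cutoff = mean + age_sd_mult * sd
    else:
        cutoff = float(age_cutoff)
    outlier = eligible & ~too_missing & (ages > cutoff)
    for pid in data.items.index[outlier]:
        reasons[pid] = "age_outlier"

    keep = data.items.index[~data.items.index.isin(list(reasons))]
    if len(keep) == 0:
        raise EmptyCohortError("every participant was excluded")
    log = pd.DataFrame(
        {"id": list(reasons), "reason": [reasons[k] for k in reasons]}
    )
    log.attrs["age_cutoff"] = float(cutoff)
    kept = LikertDataset(data.items.loc[keep], list(data.specs))
    return kept, ages.loc[keep], log


def impute(
    data: LikertDataset,
    m: int = 5,
    iterations: int = 10,
    seed: int | None = None,
    pmm_k: int = 5,
) -> list[LikertDataset]:
    """Multiple imputation by chained equations with predictive mean matching.

    Each of the ``m`` chains starts from a random hot-deck fill, then cycles
    ``iterations`` times over incomplete columns, regressing the observed
    values on all other (currently completed) columns by least squares and
    replacing each missing cell with the observed value of one of the
    ``pmm_k`` donors whose predictions are closest.  Observed cells are never
    altered, and imputed values always lie in the column's observed support.
    """
    X = data.items.to_numpy(dtype=float)
    n, q = X.shape
    miss = np.isnan(X)
    col_has_missing = miss.any(axis=0)
    for j in np.where((~miss).sum(axis=0) < 2)[0]:
        raise ValueError(f"column {data.items.columns[j]} has fewer than 2 observed values")
    rng = np.random.default_rng(seed)
    out: list[LikertDataset] = []
    for _ in range(m):
        Xc = X.copy()
        # hot-deck initialization
        for j in np.where(col_has_missing)[0]:
            obs = X[~miss[:, j], j]
            Xc[miss[:, j], j] = rng.choice(obs, size=miss[:, j].sum(), replace=True)
        for _ in range(iterations if col_has_missing.any() else 0):
            for j in np.where(col_has_missing)[0]:
                obs_rows = ~miss[:, j]
                y = X[obs_rows, j]
                if np.ptp(y) == 0:  # constant column: impute its mode
                    warnings.warn(
                        f"constant column {data.items.columns[j]}; imputing by mode",
                        stacklevel=2,
                    )
                    Xc[miss[:, j], j] = y[0]
                    continue
                others = np.delete(np.arange(q), j)
                A = np.column_stack([np.ones(n), Xc[:, others]])
                beta, *_ = np.linalg.lstsq(A[obs_rows], y, rcond=None)
                pred = A @ beta
                pred_obs = pred[obs_rows]
                pred_mis = pred[miss[:, j]]
                # k nearest observed predictions donate their observed value
                order = np.argsort(pred_obs, kind="stable")
                pos = np.searchsorted(pred_obs[order], pred_mis)
                donors = np.empty(len(pred_mis))
                for t, c in enumerate(pos):
                    lo = max(0, c - pmm_k)
                    hi = min(len(order), c + pmm_k)
                    window = order[lo:hi]
                    dist = np.abs(pred_obs[window] - pred_mis[t])
                    nearest = window[np.argsort(dist, kind="stable")[:pmm_k]]
                    donors[t] = y[nearest[rng.integers(0, len(nearest))]]
                Xc[miss[:, j], j] = donors
        out.append(
            LikertDataset(
                pd.DataFrame(Xc, index=data.items.index, columns=data.items.columns),
                list(data.specs),
            )
        )
    return out


def score_scales(items: pd.DataFrame, specs: list[ScaleSpec]) -> pd.DataFrame:
    """Sum item responses into scale totals, un-flipping reverse-keyed items."""
    totals = {}
    for spec in specs:
        block = items[spec.item_columns()].to_numpy(dtype=float)
        if np.isnan(block).any():
            raise ValueError(f"{spec.name}: missing values present; impute first")
        lo, hi = spec.item_min, spec.item_max
        if (block < lo).any() or (block > hi).any():
            r, c = np.argwhere((block < lo) | (block > hi))[0]
            raise ValueError(
                f"{spec.name}: response out of range at row {items.index[r]}, item {c + 1}"
            )
        for i in spec.reverse_items:
            block[:, i - 1] = lo + hi - block[:, i - 1]
        totals[spec.name] = block.sum(axis=1)
    return pd.DataFrame(totals, index=items.index)


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance).

    Sample variances use the n-1 denominator.  Reverse-keyed items should be
    un-flipped before calling (alpha is computed on scoring-direction items).
    """
    X = np.asarray(items, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if n < 3:
        raise ValueError("alpha needs at least 3 rows")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("zero total-score variance; alpha undefined")
    return k / (k - 1) * (1 - X.var(axis=0, ddof=1).sum() / total_var)


def gaussianize(totals: pd.DataFrame) -> pd.DataFrame:
    """Rank-based inverse-normal transform, column-wise.

    Ties receive average ranks; ranks are mapped through
    ``Phi^-1((rank - 0.5) / n)`` and then centered/scaled to exact sample
    mean 0 and SD 1.  The map is strictly monotone (weakly under ties).
    """
    out = {}
    n = len(totals)
    for col in totals.columns:
        x = totals[col].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            raise ValueError(f"column {col} is constant; cannot gaussianize")
        z = ndtri((rankdata(x, method="average") - 0.5) / n)
        z = (z - z.mean()) / z.std(ddof=0)
        out[col] = z
    return pd.DataFrame(out, index=totals.index)


def preprocess_study(
    data: LikertDataset,
    ages: pd.Series,
    m: int = 5,
    iterations: int = 10,
    seed: int | None = None,
    max_missing_frac: float = 0.20,
    age_sd_mult: float = 2.0,
    min_age: int = 18,
) -> tuple[CleanDataset, list[CleanDataset]]:
    """Full cleaning pipeline; returns (primary, per-imputation list).

    The primary :class:`CleanDataset` holds the first completed dataset's
    totals and z-scores; the full list supports pooling strategies (e.g.
    averaging correlation matrices over imputations) downstream.
    """
    kept, kept_ages, log = filter_participants(
        data, ages, max_missing_frac=max_missing_frac, age_sd_mult=age_sd_mult, min_age=min_age
    )
    completed = impute(kept, m=m, iterations=iterations, seed=seed)
    cleans = []
    for comp in completed:
        totals = score_scales(comp.items, comp.specs)
        z = gaussianize(totals)
        cleans.append(CleanDataset(totals, z, list(comp.items.index), log))
    return cleans[0], cleans
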