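"""Questionnaire scale metadata.

A study battery is a list of :class:`ScaleSpec` objects, one per construct.
The default battery mirrors a 12-construct dissociation survey: the felt-sense-
of-anomaly dissociation scale plus eleven candidate psychological mechanisms,
with the published item counts, response ranges and internal consistencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ScaleSpec:
    """Metadata for one multi-item Likert scale.

    Parameters
    ----------
    name:
        Short construct label, used as a column-name prefix (``<name>_<item>``).
    n_items:
        Number of items summed into the scale total.
    item_min, item_max:
        Inclusive response range of each item.
    reverse_items:
        1-based indices of reverse-keyed items.  Scoring maps a response ``v``
        on these items to ``item_min + item_max - v`` before summation.
    """

    name: str
    n_items: int
    item_min: int
    item_max: int
    reverse_items: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError(f"{self.name}: n_items must be positive")
        if self.item_max <= self.item_min:
            raise ValueError(f"{self.name}: empty item response range")
        bad = set(self.reverse_items) - set(range(1, self.n_items + 1))
        if bad:
            raise ValueError(f"{self.name}: reverse_items {sorted(bad)} out of 1..{self.n_items}")

    @property
    def score_range(self) -> tuple[int, int]:
        """Attainable (min, max) of the scale total."""
        return self.n_items * self.item_min, self.n_items * self.item_max

    @property
    def n_categories(self) -> int:
        return self.item_max - self.item_min + 1

    def item_columns(self) -> list[str]:
        return [f"{self.name}_{i}" for i in range(1, self.n_items + 1)]


def reliability_from_alpha(alpha: float, k: int) -> float:
    """Invert the one-factor Cronbach's-alpha formula to an item loading.

    Under a single common factor with equal standardized loadings lambda,
    alpha = k*lambda^2 / (1 + (k-1)*lambda^2); this returns lambda.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lam2 = alpha / (k - (k - 1) * alpha)
    return math.sqrt(lam2)


# The 12-construct survey battery: (spec, published Cronbach's alpha).
# Reverse-keyed items are present in the attentional-control scale and one
# item of the alexithymia questionnaire.
_BATTERY: list[tuple[ScaleSpec, float]] = [
    (ScaleSpec("dissociation", 35, 0, 4), 0.97),   # felt-sense-of-anomaly scale, 0-140
    (ScaleSpec("cad", 13, 0, 4), 0.93),            # cognitive appraisals of dissociation, 0-52
    (ScaleSpec("rtd", 6, 0, 4), 0.67),             # responses to dissociation, 0-24
    (ScaleSpec("ais", 30, 1, 6), 0.95),            # affect intolerance, 30-180
    (ScaleSpec("asi", 18, 0, 4), 0.93),            # anxiety sensitivity, 0-72
    (ScaleSpec("atc", 20, 1, 4, frozenset({1, 5, 9, 13})), 0.87),  # attentional control, 20-80
    (ScaleSpec("bvs", 4, 0, 10), 0.93),            # body vigilance, 0-40
    (ScaleSpec("gse", 10, 1, 4), 0.92),            # general self-efficacy, 10-40
    (ScaleSpec("mes", 11, 1, 6), 0.89),            # negative meta-emotion, 11-66
    (ScaleSpec("oaq", 11, 1, 5, frozenset({2})), 0.84),  # alexithymia, 11-55
    (ScaleSpec("ptq", 15, 0, 4), 0.97),            # perseverative thinking, 0-60
    (ScaleSpec("ovw", 8, 0, 4), 0.90),             # beliefs about being overwhelmed, 0-32
]


def study_scales() -> list[ScaleSpec]:
    """The default 12-construct battery."""
    return [spec for spec, _ in _BATTERY]


def study_reliabilities() -> dict[str, float]:
    """Per-scale item loadings implied by the published alphas."""
    return {spec.name: reliability_from_alpha(alpha, spec.n_items) for spec, alpha in _BATTERY}
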