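"""Built-in calibrated parameter sets and a synthetic model generator.

Two in-literature fixtures make every stage of the pipeline runnable
without external data:

* a six-item bifactor demonstration scale (three clusters of two items,
  standard-normal priors, the classic hand-checkable example), and
* a two-grade-band English language proficiency (ELPA21-style) listening
  assessment: 24 + 30 dichotomous items, two correlated primary
  proficiency dimensions, all specific loadings zero, plus the operational
  achievement-level cut scores.

``synth_model`` draws reproducible random two-tier models for stress and
property testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ItemParams, TwoTierModel

__all__ = ["FixtureSpec", "sixitem_fixture", "elpa21_fixture", "synth_model"]


@dataclass
class FixtureSpec:
    name: str
    model: TwoTierModel
    grid_Q: int
    grid_bounds: tuple[float, float]
    cut_scores: dict[str, tuple[float, ...]] = field(default_factory=dict)
    note: str = ""


def sixitem_fixture() -> FixtureSpec:
    """Six-item bifactor scale: M=1, three two-item clusters.

    The recommended grid is the five-point demonstration grid at
    -2..2 used in the worked tables; production use wants a much denser
    grid.
    """
    rows = [
        ("i1", 1, -1.0, 1.2, 1.0),
        ("i2", 1, -0.6, 1.2, 1.0),
        ("i3", 2, -0.2, 1.0, 0.8),
        ("i4", 2, 0.2, 1.0, 0.8),
        ("i5", 3, 0.6, 0.8, 1.2),
        ("i6", 3, 1.0, 0.8, 1.2),
    ]
    items = [
        ItemParams(item_id=i, cluster=n, intercept=c, primary_slopes=(a0,), specific_slope=a1)
        for i, n, c, a0, a1 in rows
    ]
    model = TwoTierModel(items=items, M=1, N=3)
    return FixtureSpec(
        name="sixitem",
        model=model,
        grid_Q=5,
        grid_bounds=(-2.0, 2.0),
        note="hypothetical six-item bifactor scale; standard normal priors",
    )


# (intercept, slope) per item; lower band loads on eta_1, upper on eta_2
_ELPA_LOWER = [
    (3.26, 1.43), (2.95, 1.53), (1.10, 0.46), (2.85, 1.88), (1.95, 1.51),
    (1.59, 1.10), (2.82, 1.50), (4.02, 1.64), (0.18, 0.29), (2.08, 1.27),
    (2.24, 1.28), (1.70, 0.95), (4.34, 1.71), (2.80, 1.52), (3.77, 2.10),
    (2.96, 1.80), (3.33, 1.79), (0.33, 0.76), (-0.95, 0.57), (2.18, 1.46),
    (1.79, 1.20), (1.78, 1.57), (2.49, 1.65), (1.38, 1.01),
]
_ELPA_UPPER = [
    (1.60, 1.48), (0.98, 1.54), (2.34, 1.73), (1.65, 1.42), (2.20, 1.64),
    (0.89, 1.10), (2.94, 2.03), (2.70, 1.32), (5.40, 2.64), (3.51, 2.24),
    (5.40, 2.73), (4.34, 2.16), (4.09, 2.14), (6.03, 2.04), (5.76, 2.95),
    (4.94, 2.10), (4.71, 2.56), (7.92, 2.95), (2.67, 1.66), (2.45, 1.81),
    (0.66, 1.49), (2.14, 1.74), (1.51, 1.81), (1.93, 1.39), (2.51, 1.90),
    (2.72, 1.86), (3.85, 2.31), (0.35, 0.73), (2.28, 1.65), (1.39, 1.26),
]


def elpa21_fixture() -> FixtureSpec:
    """Two-grade-band listening assessment as a two-tier model.

    The correlated-traits longitudinal MIRT model (M=2) is cast as a
    two-tier model with empty specific dimensions: each form is a cluster
    whose items carry zero specific loading, so the score-combination
    machinery applies unchanged.  Prior: estimated population distribution
    with means (.09, -.05), variances (1.25, .62) and covariance .80
    (correlation about .91).  Cut scores split each band's scale into
    emerging / progressing / proficient.
    """
    items = [
        ItemParams(f"Lower{i + 1}", 1, c, (a, 0.0), 0.0)
        for i, (c, a) in enumerate(_ELPA_LOWER)
    ] + [
        ItemParams(f"Upper{i + 1}", 2, c, (0.0, a), 0.0)
        for i, (c, a) in enumerate(_ELPA_UPPER)
    ]
    model = TwoTierModel(
        items=items,
        M=2,
        N=2,
        prior_eta_mean=np.array([0.09, -0.05]),
        prior_eta_cov=np.array([[1.25, 0.80], [0.80, 0.62]]),
    )
    return FixtureSpec(
        name="elpa21",
        model=model,
        grid_Q=49,
        grid_bounds=(-6.0, 6.0),
        cut_scores={
            "lower": (-1.1875, -0.65),
            "upper": (-1.375, -0.65),
        },
        note="two adjacent grade-band listening forms; zero specific loadings",
    )


def synth_model(
    seed: int,
    M: int = 1,
    N: int = 3,
    items_per_cluster: int | tuple[int, ...] = 2,
    slope_range: tuple[float, float] = (0.5, 2.5),
    intercept_range: tuple[float, float] = (-2.0, 2.0),
) -> TwoTierModel:
    """Draw a reproducible random two-tier model.

    Slopes are uniform on ``slope_range`` (positive by default, keeping
    response functions monotone in each dimension), intercepts uniform on
    ``intercept_range``.  ``items_per_cluster`` may be a scalar or one
    count per cluster.
    """
    if M < 1 or N < 1:
        raise ValueError("M and N must be positive")
    if np.isscalar(items_per_cluster):
        counts = (int(items_per_cluster),) * N
    else:
        counts = tuple(int(k) for k in items_per_cluster)
    if len(counts) != N or any(k < 1 for k in counts):
        raise ValueError("need a positive item count for each of the N clusters")
    if not (slope_range[0] < slope_range[1] and intercept_range[0] < intercept_range[1]):
        raise ValueError("invalid parameter ranges")
    rng = np.random.default_rng(seed)
    items = []
    for n, k in enumerate(counts, start=1):
        for j in range(k):
            items.append(
                ItemParams(
                    item_id=f"c{n}_i{j + 1}",
                    cluster=n,
                    intercept=float(rng.uniform(*intercept_range)),
                    primary_slopes=tuple(float(a) for a in rng.uniform(*slope_range, size=M)),
                    specific_slope=float(rng.uniform(*slope_range)),
                )
            )
    return TwoTierModel(items=items, M=M, N=N)
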