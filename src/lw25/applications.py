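"""Downstream procedures built on score-combination posteriors.

Three reporting tools:

* **Growth classification** — probability that a student with an observed
  score combination falls in each achievement region (e.g., emerging /
  progressing / proficient) of each grade band, from the volume of the
  marginal posterior between cut scores, plus combination probabilities,
  marginal score probabilities and observed-score conditional percentiles
  (a growth-percentile analogue).
* **Subscore screening** — regress each combination's specific-dimension
  estimate on its primary estimate, weighted by combination probability;
  combinations whose posterior mass falls mostly outside the prediction
  band carry subscore information worth reporting.
* **HDR aberrance detection** — the smallest set of score combinations
  covering a target probability; combinations outside it are flagged as
  rarely co-occurring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal
from scipy.stats import norm as _norm

from .posteriors import ComboPosterior, ComboTable, normal_approx

__all__ = [
    "CutScores",
    "RegressionBand",
    "HDRResult",
    "classify_regions",
    "conditional_percentile",
    "marginal_score_prob",
    "subscore_screen",
    "hdr",
]

DimSelector = int | Literal["xi"]


@dataclass(frozen=True)
class CutScores:
    """Ordered cut points on one latent scale; K cuts define K+1 regions."""

    cuts: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.cuts) == 0 or np.any(np.diff(self.cuts) <= 0):
            raise ValueError("cut scores must be strictly increasing and nonempty")
        if self.labels is not None and len(self.labels) != len(self.cuts) + 1:
            raise ValueError("need one label per region (K cuts -> K+1 regions)")

    @property
    def n_regions(self) -> int:
        return len(self.cuts) + 1

    def region_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return self.labels
        return tuple(f"region{i}" for i in range(self.n_regions))


def _joint(ct: ComboTable | np.ndarray) -> np.ndarray:
    if isinstance(ct, ComboTable):
        return ct.prob_matrix
    return np.asarray(ct, dtype=float)


def _region_probs_quadrature(
    cp: ComboPosterior, dim: DimSelector, cuts: CutScores
) -> np.ndarray:
    if dim == "xi":
        pts = cp.xi_grid.points[0]
        w = cp.xi_marginal_weights()
    else:
        pts = cp.eta_grid.points[dim]
        w = cp.eta_marginal_weights(dim)
    regions = np.searchsorted(np.asarray(cuts.cuts), pts, side="right")
    return np.bincount(regions, weights=w, minlength=cuts.n_regions)


def _region_probs_normal(
    cp: ComboPosterior, dim: DimSelector, cuts: CutScores
) -> np.ndarray:
    idx = len(cp.mu) - 1 if dim == "xi" else dim
    mean, sd = cp.mu[idx], np.sqrt(cp.sigma[idx, idx])
    edges = np.concatenate([[-np.inf], cuts.cuts, [np.inf]])
    cdf = _norm.cdf(edges, mean, sd)
    return np.diff(cdf)


def classify_regions(
    ct: ComboTable,
    cuts: dict[DimSelector, CutScores],
    mode: Literal["quadrature", "normal"] = "quadrature",
) -> pd.DataFrame:
    """Achievement-region probabilities for every score combination.

    ``cuts`` maps a dimension selector (primary-dimension index, or
    ``"xi"`` for the focal specific dimension) to its cut scores.  Each
    output row holds the region probabilities (summing to one) of one
    combination on one dimension, computed from the marginal posterior —
    by summing quadrature weights between cuts (default) or from normal
    CDF differences (``mode="normal"``).  Combinations with zero
    probability yield NaN rows.
    """
    for dim, cs in cuts.items():
        if dim != "xi":
            lo, hi = ct.combos[0].eta_grid.points[dim][[0, -1]]
            if np.min(cs.cuts) < lo or np.max(cs.cuts) > hi:
                warnings.warn(
                    f"cut score outside grid range [{lo}, {hi}] on dimension {dim}"
                )
    rows = []
    for cp in ct.combos:
        for dim, cs in cuts.items():
            row = {"s_n": cp.score, "s_rest": cp.rest_score, "dim": str(dim),
                   "prob": cp.prob}
            if cp.prob <= 0.0 or cp.weights is None:
                probs = np.full(cs.n_regions, np.nan)
            elif mode == "quadrature":
                probs = _region_probs_quadrature(cp, dim, cs)
            elif mode == "normal":
                probs = _region_probs_normal(cp, dim, cs)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            for lab, p in zip(cs.region_labels(), probs):
                row[lab] = p
            rows.append(row)
    return pd.DataFrame(rows)


def marginal_score_prob(
    ct: ComboTable | np.ndarray, which: Literal["focal", "rest"], score: int
) -> float:
    """Marginal probability of one observed score, p(s) = sum over the
    other side's scores of p(s_n, s_(n))."""
    joint = _joint(ct)
    axis = 0 if which == "focal" else 1
    n = joint.shape[axis]
    if not 0 <= score < n:
        raise ValueError(f"score {score} out of range 0..{n - 1}")
    return float(joint.take(score, axis=axis).sum())


def conditional_percentile(
    ct: ComboTable | np.ndarray,
    given: int,
    at: int,
    given_side: Literal["focal", "rest"] = "focal",
    rule: Literal["le", "lt", "midpoint"] = "le",
) -> float:
    """Percentile of a score on one side among examinees with a fixed
    score on the other side.

    Returns ``100 * P(other <= at | given side = given)`` under the
    default cumulative rule; ``rule="lt"`` uses the percent scoring
    strictly below (the growth-percentile reading of an observed score),
    and ``rule="midpoint"`` the midpoint convention
    ``100 * (P(< at) + P(= at)/2 | given)``.
    """
    joint = _joint(ct)
    cond = joint[given, :] if given_side == "focal" else joint[:, given]
    marg = cond.sum()
    if marg <= 0.0:
        raise ValueError("conditioning score has zero marginal probability")
    if not 0 <= at < len(cond):
        raise ValueError(f"score {at} out of range 0..{len(cond) - 1}")
    if rule == "le":
        mass = cond[: at + 1].sum()
    elif rule == "lt":
        mass = cond[:at].sum()
    elif rule == "midpoint":
        mass = cond[:at].sum() + 0.5 * cond[at]
    else:
        raise ValueError(f"unknown percentile rule {rule!r}")
    return float(100.0 * mass / marg)


@dataclass(frozen=True)
class RegressionBand:
    """Probability-weighted least-squares fit of mu_n on mu_0 with a
    prediction band.

    The half-width at x is ``z * sqrt(s2 * (1 + h(x)))`` where ``s2`` is
    the weighted residual variance (weights scaled to sum to the number of
    points, normal-theory df correction) and ``h(x)`` the WLS leverage of
    a new point at x.
    """

    intercept: float
    slope: float
    s2: float
    xtwx_inv: np.ndarray  # (2, 2) for the leverage term
    level: float

    def predict(self, x: np.ndarray | float) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def half_width(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        X = np.stack([np.ones_like(x), x], axis=-1)
        h = np.einsum("...i,ij,...j->...", X, self.xtwx_inv, X)
        z = _norm.ppf(0.5 * (1.0 + self.level))
        return z * np.sqrt(self.s2 * (1.0 + h))

    def lower(self, x):
        return self.predict(x) - self.half_width(x)

    def upper(self, x):
        return self.predict(x) + self.half_width(x)


def _fit_band(x: np.ndarray, y: np.ndarray, w: np.ndarray, level: float) -> RegressionBand:
    n = len(x)
    w = w * (n / w.sum())  # scale weights to sum to n
    X = np.column_stack([np.ones(n), x])
    XtW = X.T * w
    xtwx = XtW @ X
    if np.linalg.cond(xtwx) > 1e12 or np.ptp(x) == 0:
        raise ValueError("degenerate regression: no spread in primary estimates")
    beta = np.linalg.solve(xtwx, XtW @ y)
    resid = y - X @ beta
    s2 = float((w * resid**2).sum() / (n - 2))
    return RegressionBand(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        s2=s2,
        xtwx_inv=np.linalg.inv(xtwx),
        level=level,
    )


def _band_volume(
    cp: ComboPosterior, band: RegressionBand, n_grid: int = 201, span: float = 6.0
) -> float:
    """Mass of the bivariate normal approximation lying inside the band.

    Midpoint rule on an n_grid x n_grid box spanning +-span posterior SDs
    around the mean in the (primary, specific) plane.
    """
    na = normal_approx(cp)
    sds = np.sqrt(np.diag(na.cov))
    xs = np.linspace(na.mean[0] - span * sds[0], na.mean[0] + span * sds[0], n_grid)
    ys = np.linspace(na.mean[1] - span * sds[1], na.mean[1] + span * sds[1], n_grid)
    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    dens = multivariate_normal.pdf(
        np.stack([gx, gy], axis=-1), mean=na.mean, cov=na.cov
    )
    inside = (gy >= band.lower(gx)) & (gy <= band.upper(gx))
    return float(min(1.0, (dens * inside).sum() * dx * dy))


def subscore_screen(
    ct: ComboTable, level: float = 0.95
) -> tuple[RegressionBand, pd.DataFrame]:
    """Screen a focal cluster's subscore for added value.

    Fits the probability-weighted regression of the specific-dimension
    estimate mu_n on the primary estimate mu_0 across all combinations,
    builds the prediction band at ``level``, and computes for every
    combination the proportion of its (bivariate-normal-approximated)
    posterior volume inside the band.  Small proportions mark score
    combinations whose subscore disagrees with the overall score — the
    ones worth reporting.
    """
    if ct.M != 1:
        raise ValueError("subscore screening is defined for M = 1 models")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    ok = [c for c in ct.combos if c.prob > 0 and np.all(np.isfinite(c.mu))]
    if len(ok) < 3:
        raise ValueError("need at least 3 combinations with positive probability")
    x = np.array([c.mu[0] for c in ok])
    y = np.array([c.mu_n for c in ok])
    w = np.array([c.prob for c in ok])
    band = _fit_band(x, y, w / w.sum(), level)
    rows = [
        {
            "s_n": c.score,
            "s_rest": c.rest_score,
            "prob": c.prob,
            "mu0": c.mu[0],
            "mu_n": c.mu_n,
            "volume_in_band": _band_volume(c, band),
        }
        for c in ok
    ]
    return band, pd.DataFrame(rows)


@dataclass
class HDRResult:
    """High-density region over score combinations at one coverage level."""

    alpha: float
    table: pd.DataFrame  # columns s_n, s_rest, prob, included, cum_prob
    coverage: float

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["included"]]

    @property
    def excluded(self) -> pd.DataFrame:
        return self.table[~self.table["included"]]


def hdr(ct: ComboTable | np.ndarray, alpha: float = 0.95) -> HDRResult:
    """High-density region of the score-combination distribution.

    Stacks all p(s_n, s_(n)), sorts them descending (ties broken
    deterministically by (s_n, s_(n)) lexicographic order), and
    accumulates until the running total reaches ``alpha``; the crossing
    combination is included and nothing after it, so the region is a
    minimal top-probability set.  Everything outside the region is an
    unusually rare score combination.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    joint = _joint(ct)
    s_n, s_r = np.meshgrid(
        np.arange(joint.shape[0]), np.arange(joint.shape[1]), indexing="ij"
    )
    df = pd.DataFrame(
        {"s_n": s_n.ravel(), "s_rest": s_r.ravel(), "prob": joint.ravel()}
    )
    df = df.sort_values(
        ["prob", "s_n", "s_rest"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    cum = df["prob"].cumsum()
    k = int(np.searchsorted(cum.values, alpha - 1e-12))  # first index with cum >= alpha
    k = min(k, len(df) - 1)
    included = np.arange(len(df)) <= k
    df["included"] = included
    df["cum_prob"] = cum
    return HDRResult(alpha=alpha, table=df, coverage=float(df.loc[included, "prob"].sum()))
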