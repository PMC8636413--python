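"""Two-tier item factor models, priors, and rectangular quadrature grids.

A two-tier model has M correlated primary dimensions (eta) and N mutually
independent specific dimensions (xi_1..xi_N).  Every item loads on the
primary dimensions and on at most one specific dimension; the items sharing
specific dimension n form *item cluster* n.  The bifactor model is the M=1
special case; a correlated-traits MIRT model is the case where every
specific slope is zero.

Item responses are dichotomous with a logistic response function

    T(1 | eta, xi_n) = logistic(c + a0 . eta + a_n * xi_n)

where ``c`` is the intercept, ``a0`` the vector of primary slopes and
``a_n`` the specific slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import multivariate_normal, norm

__all__ = [
    "ItemParams",
    "TwoTierModel",
    "QuadratureGrid",
    "item_response",
    "make_grid",
    "make_xi_grid",
]


@dataclass(frozen=True)
class ItemParams:
    """Parameters of one dichotomous item.

    ``cluster`` is the 1-based index of the specific dimension the item
    loads on; 0 means the item loads on the primary dimensions only (its
    ``specific_slope`` is ignored).
    """

    item_id: str
    cluster: int
    intercept: float
    primary_slopes: tuple[float, ...]
    specific_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.cluster < 0:
            raise ValueError(f"item {self.item_id!r}: cluster must be >= 0")
        vals = (self.intercept, self.specific_slope, *self.primary_slopes)
        if not all(np.isfinite(vals)):
            raise ValueError(f"item {self.item_id!r}: non-finite parameter")


@dataclass
class TwoTierModel:
    """A calibrated two-tier model: items, cluster structure and priors.

    Parameters
    ----------
    items
        Item parameter records.  All must have ``len(primary_slopes) == M``
        and ``cluster <= N``.
    M, N
        Number of primary and specific dimensions.  Empty clusters (no item
        with that index) are allowed.
    prior_eta_mean, prior_eta_cov
        Mean vector (length M) and covariance (M x M, symmetric positive
        definite) of the multivariate-normal prior h(eta).  Defaults:
        standard normal.
    prior_xi
        Optional per-cluster ``(mean, variance)`` of the normal prior
        g(xi_n); clusters absent from the mapping use the standard normal.
    """

    items: list[ItemParams]
    M: int = 1
    N: int = 0
    prior_eta_mean: np.ndarray = None  # type: ignore[assignment]
    prior_eta_cov: np.ndarray = None  # type: ignore[assignment]
    prior_xi: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.prior_eta_mean is None:
            self.prior_eta_mean = np.zeros(self.M)
        if self.prior_eta_cov is None:
            self.prior_eta_cov = np.eye(self.M)
        self.prior_eta_mean = np.asarray(self.prior_eta_mean, dtype=float)
        self.prior_eta_cov = np.asarray(self.prior_eta_cov, dtype=float)
        if self.prior_eta_mean.shape != (self.M,):
            raise ValueError("prior_eta_mean must have length M")
        if self.prior_eta_cov.shape != (self.M, self.M):
            raise ValueError("prior_eta_cov must be M x M")
        if not np.allclose(self.prior_eta_cov, self.prior_eta_cov.T):
            raise ValueError("prior covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.prior_eta_cov) <= 0):
            raise ValueError("prior covariance must be positive definite")
        for it in self.items:
            if len(it.primary_slopes) != self.M:
                raise ValueError(
                    f"item {it.item_id!r}: expected {self.M} primary slopes, "
                    f"got {len(it.primary_slopes)}"
                )
            if it.cluster > self.N:
                raise ValueError(
                    f"item {it.item_id!r}: cluster {it.cluster} > N={self.N}"
                )

    # -- cluster structure helpers ------------------------------------
    def cluster_items(self, n: int) -> list[ItemParams]:
        """Items in cluster ``n`` (0 = items with no specific loading)."""
        return [it for it in self.items if it.cluster == n]

    def cluster_size(self, n: int) -> int:
        return len(self.cluster_items(n))

    @property
    def clusters(self) -> list[int]:
        """Cluster indices with at least one item, in ascending order."""
        present = sorted({it.cluster for it in self.items})
        return present

    @property
    def max_score(self) -> int:
        return len(self.items)

    def xi_prior(self, n: int) -> tuple[float, float]:
        return self.prior_xi.get(n, (0.0, 1.0))


@dataclass(frozen=True)
class QuadratureGrid:
    """Rectangular quadrature grid with normalized prior-ordinate weights.

    ``points`` holds one strictly increasing point array per dimension; the
    grid is their direct product.  ``nodes`` is the (K, d) array of product
    nodes in row-major (last dimension fastest) order and ``weights`` the
    matching nonnegative weights summing to one.
    """

    points: tuple[np.ndarray, ...]
    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        for p in self.points:
            if len(p) < 2 or np.any(np.diff(p) <= 0):
                raise ValueError("grid points must be strictly increasing, Q >= 2")
        if np.any(self.weights < 0):
            raise ValueError("negative quadrature weight")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("quadrature weights must sum to 1")

    @property
    def ndim(self) -> int:
        return len(self.points)

    @property
    def size(self) -> int:
        return self.nodes.shape[0]

    def marginal_weights(self, dim: int, weights: np.ndarray | None = None) -> np.ndarray:
        """Collapse product-grid ``weights`` onto the points of one dimension."""
        w = self.weights if weights is None else np.asarray(weights)
        shape = tuple(len(p) for p in self.points)
        axes = tuple(d for d in range(self.ndim) if d != dim)
        return w.reshape(shape).sum(axis=axes)


def _product_nodes(points: Sequence[np.ndarray]) -> np.ndarray:
    mesh = np.meshgrid(*points, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def item_response(
    item: ItemParams, eta: Sequence[float] | np.ndarray, xi: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the item response function; returns ``(T(0), T(1))``.

    ``eta`` is a length-M vector (or an array whose last axis has length M)
    and ``xi`` the value of the item's specific dimension, broadcastable
    against the leading axes of ``eta``.  Items with ``cluster == 0`` ignore
    ``xi``.
    """
    eta = np.asarray(eta, dtype=float)
    a0 = np.asarray(item.primary_slopes)
    if eta.shape[-1:] != (len(a0),):
        raise ValueError(
            f"eta has trailing dimension {eta.shape[-1:]}, expected {len(a0)}"
        )
    z = item.intercept + eta @ a0
    if item.cluster != 0:
        z = z + item.specific_slope * np.asarray(xi, dtype=float)
    t1 = expit(z)
    return 1.0 - t1, t1


def equally_spaced(Q: int, lo: float, hi: float) -> np.ndarray:
    if Q < 2:
        raise ValueError("Q must be >= 2")
    if not lo < hi:
        raise ValueError("grid range must satisfy lo < hi")
    return np.linspace(lo, hi, Q)


def make_grid(
    model: TwoTierModel, Q: int = 49, bounds: tuple[float, float] = (-6.0, 6.0)
) -> QuadratureGrid:
    """Quadrature grid for the primary dimensions eta.

    Equally spaced points per dimension; product-grid weights are the
    multivariate-normal prior ordinates normalized to sum to one, so a
    correlated prior induces correlated weights.
    """
    pts = equally_spaced(Q, *bounds)
    points = tuple(pts.copy() for _ in range(model.M))
    nodes = _product_nodes(points)
    dens = multivariate_normal.pdf(
        nodes, mean=model.prior_eta_mean, cov=model.prior_eta_cov
    )
    dens = np.atleast_1d(dens)
    return QuadratureGrid(points=points, nodes=nodes, weights=dens / dens.sum())


def make_xi_grid(
    model: TwoTierModel,
    cluster: int,
    Q: int = 49,
    bounds: tuple[float, float] = (-6.0, 6.0),
) -> QuadratureGrid:
    """Univariate grid for specific dimension ``cluster`` with normalized
    ordinates of its normal prior g(xi_n)."""
    pts = equally_spaced(Q, *bounds)
    mean, var = model.xi_prior(cluster)
    dens = norm.pdf(pts, loc=mean, scale=np.sqrt(var))
    return QuadratureGrid(
        points=(pts,), nodes=pts[:, None], weights=dens / dens.sum()
    )
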