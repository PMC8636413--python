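"""Posterior objects for summed scores and score combinations.

Two layers of scoring output:

* total-score posteriors p(eta | s), one per overall summed score, with
  EAP mean and error variance — the classic summed-score-to-scale-score
  conversion table;
* score-combination posteriors p(eta, xi_n | s_n, s_(n)) for a focal
  cluster n, indexed by the pair (within-cluster score, rest score), with
  mean vector mu = (mu_0, mu_n) and covariance Sigma collecting
  sigma_00, sigma_0n and sigma_nn.

All moments are computed from the discrete quadrature posterior; the
normal approximation built from (mu, Sigma) is a downstream convenience
for plotting and region/band probabilities, never the source of moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .lw_recursions import (
    ScoreLikelihoodTable,
    rest_score_likelihoods,
    stage1_tables,
    total_score_likelihoods,
)
from .model_core import QuadratureGrid, TwoTierModel

__all__ = [
    "TotalScorePosterior",
    "ComboPosterior",
    "ComboTable",
    "NormalApprox",
    "lw20_posteriors",
    "combo_posteriors",
    "normal_approx",
]


@dataclass
class TotalScorePosterior:
    """Posterior of the primary dimensions given one total summed score."""

    score: int
    prob: float
    weights: np.ndarray  # normalized, over eta product-grid nodes
    eta_grid: QuadratureGrid
    mean: np.ndarray  # (M,)
    cov: np.ndarray  # (M, M)

    @property
    def variance(self) -> float:
        """Var(eta | s) for M = 1 models, as a scalar convenience."""
        return float(self.cov[0, 0])


@dataclass
class ComboPosterior:
    """Joint posterior of (eta, xi_n) given a score combination.

    ``mu`` stacks the M primary means and the specific mean last;
    ``sigma`` is the matching (M+1) x (M+1) covariance.  A combination
    with numerically zero marginal probability keeps its slot with
    ``prob = 0`` and NaN moments so table shapes stay predictable.
    """

    focal: int
    score: int
    rest_score: int
    prob: float
    weights: np.ndarray | None  # (K, Q_xi) normalized, None if impossible
    eta_grid: QuadratureGrid
    xi_grid: QuadratureGrid
    mu: np.ndarray  # (M + 1,)
    sigma: np.ndarray  # (M + 1, M + 1)

    @property
    def mu0(self) -> np.ndarray:
        return self.mu[:-1]

    @property
    def mu_n(self) -> float:
        return float(self.mu[-1])

    @property
    def sigma00(self) -> np.ndarray:
        return self.sigma[:-1, :-1]

    @property
    def sigma_nn(self) -> float:
        return float(self.sigma[-1, -1])

    @property
    def sigma_0n(self) -> np.ndarray:
        return self.sigma[:-1, -1]

    def eta_marginal_weights(self, dim: int = 0) -> np.ndarray:
        """Marginal posterior over the points of primary dimension ``dim``."""
        w_eta = self.weights.sum(axis=1)  # collapse xi
        return self.eta_grid.marginal_weights(dim, w_eta)

    def xi_marginal_weights(self) -> np.ndarray:
        return self.weights.sum(axis=0)


@dataclass
class ComboTable:
    """All score-combination posteriors for one focal cluster."""

    focal: int
    combos: list[ComboPosterior]
    M: int = 1

    def __getitem__(self, key: tuple[int, int]) -> ComboPosterior:
        s_n, s_rest = key
        for cp in self.combos:
            if cp.score == s_n and cp.rest_score == s_rest:
                return cp
        raise KeyError(key)

    @property
    def prob_matrix(self) -> np.ndarray:
        """p(s_n, s_(n)) as an (S_n + 1) x (S_(n) + 1) matrix."""
        S_n = max(c.score for c in self.combos)
        S_r = max(c.rest_score for c in self.combos)
        out = np.zeros((S_n + 1, S_r + 1))
        for c in self.combos:
            out[c.score, c.rest_score] = c.prob
        return out

    def to_frame(self, decimals: int | None = 3) -> pd.DataFrame:
        """Flat summary table (one row per combination).

        For M = 1 the columns mirror the usual report layout
        ``s_n, s_rest, prob, mu0, s00, mu_n, s_nn, s0n``; for M > 1 the
        primary blocks are flattened with suffixed names (``mu0_1, ...,
        s00_11, s00_12, ...``).
        """
        rows = []
        for c in self.combos:
            row: dict[str, float] = {
                "s_n": c.score,
                "s_rest": c.rest_score,
                "prob": c.prob,
            }
            if self.M == 1:
                row["mu0"] = c.mu[0]
                row["s00"] = c.sigma[0, 0]
                row["mu_n"] = c.mu_n
                row["s_nn"] = c.sigma_nn
                row["s0n"] = c.sigma[0, -1]
            else:
                for i in range(self.M):
                    row[f"mu0_{i + 1}"] = c.mu[i]
                for i in range(self.M):
                    for j in range(i, self.M):
                        row[f"s00_{i + 1}{j + 1}"] = c.sigma[i, j]
                row["mu_n"] = c.mu_n
                row["s_nn"] = c.sigma_nn
                for i in range(self.M):
                    row[f"s0n_{i + 1}"] = c.sigma[i, -1]
            rows.append(row)
        df = pd.DataFrame(rows)
        if decimals is not None:
            num = df.columns.difference(["s_n", "s_rest"])
            df[num] = df[num].round(decimals)
        return df


def lw20_posteriors(
    model: TwoTierModel,
    eta_grid: QuadratureGrid,
    stage1=None,
) -> list[TotalScorePosterior]:
    """Total-score posteriors of eta for every summed score 0..S.

    p(eta | s) = L(s | eta) h(eta) / p(s) with p(s) and the posterior
    moments approximated on the eta grid with normalized-ordinate weights.
    """
    L = total_score_likelihoods(model, eta_grid, stage1)
    W = eta_grid.weights
    nodes = eta_grid.nodes
    out = []
    for s in range(L.n_scores):
        unnorm = L.values[s] * W
        p = float(unnorm.sum())
        if p <= 0.0:
            M = model.M
            out.append(
                TotalScorePosterior(
                    s, 0.0, None, eta_grid, np.full(M, np.nan), np.full((M, M), np.nan)
                )
            )
            continue
        w = unnorm / p
        mean = w @ nodes
        centered = nodes - mean
        cov = (centered * w[:, None]).T @ centered
        out.append(TotalScorePosterior(s, p, w, eta_grid, mean, cov))
    return out


def combo_posteriors(
    model: TwoTierModel,
    focal: int,
    eta_grid: QuadratureGrid,
    stage1=None,
) -> ComboTable:
    """Score-combination posteriors for the focal cluster.

    For each pair (s_n, s_(n)) the unnormalized posterior on the
    (eta, xi_n) product grid is

        P_n(s_n | eta, xi_n) * R_n(s_(n) | eta) * W_n(xi_n) * W(eta);

    its sum is the marginal probability p(s_n, s_(n)) and the normalized
    weights give the quadrature moments.
    """
    if stage1 is None:
        stage1 = stage1_tables(model, eta_grid)
    if focal not in stage1:
        raise ValueError(f"focal cluster {focal} has no items")
    full, _ = stage1[focal]
    rest = rest_score_likelihoods(model, focal, eta_grid, stage1)
    W_eta = eta_grid.weights
    W_xi = full.xi_grid.weights
    nodes = eta_grid.nodes  # (K, M)
    xi_pts = full.xi_grid.points[0]  # (Qx,)
    M = model.M
    combos = []
    for s_n in range(full.n_scores):
        P_w = full.values[s_n] * W_xi[None, :]  # (K, Qx)
        for s_r in range(rest.n_scores):
            unnorm = P_w * (rest.values[s_r] * W_eta)[:, None]
            p = float(unnorm.sum())
            if p <= 0.0 or not np.isfinite(p):
                combos.append(
                    ComboPosterior(
                        focal, s_n, s_r, 0.0, None, eta_grid, full.xi_grid,
                        np.full(M + 1, np.nan), np.full((M + 1, M + 1), np.nan),
                    )
                )
                continue
            w = unnorm / p
            w_eta = w.sum(axis=1)
            w_xi = w.sum(axis=0)
            mu = np.empty(M + 1)
            mu[:M] = w_eta @ nodes
            mu[M] = w_xi @ xi_pts
            cent_eta = nodes - mu[:M]  # (K, M)
            cent_xi = xi_pts - mu[M]  # (Qx,)
            sigma = np.empty((M + 1, M + 1))
            sigma[:M, :M] = (cent_eta * w_eta[:, None]).T @ cent_eta
            cross = (w * cent_xi[None, :]).sum(axis=1)  # (K,)
            sigma[:M, M] = sigma[M, :M] = cross @ cent_eta
            sigma[M, M] = w_xi @ cent_xi**2
            combos.append(
                ComboPosterior(
                    focal, s_n, s_r, p, w, eta_grid, full.xi_grid, mu, sigma
                )
            )
    return ComboTable(focal=focal, combos=combos, M=M)


@dataclass(frozen=True)
class NormalApprox:
    """Multivariate normal approximation to a combo posterior.

    Supports the axis-aligned rectangle and marginal-interval probability
    queries the downstream screening and classification procedures need.
    """

    mean: np.ndarray
    cov: np.ndarray

    @property
    def ndim(self) -> int:
        return len(self.mean)

    def rectangle_prob(self, lower, upper) -> float:
        """P(lower <= Z <= upper), componentwise, with +-inf allowed."""
        lower = np.broadcast_to(np.asarray(lower, float), (self.ndim,))
        upper = np.broadcast_to(np.asarray(upper, float), (self.ndim,))
        mvn = multivariate_normal(mean=self.mean, cov=self.cov)
        # inclusion-exclusion via the mvn CDF
        total = 0.0
        for mask in range(1 << self.ndim):
            corner = upper.copy()
            bits = 0
            for d in range(self.ndim):
                if mask >> d & 1:
                    corner[d] = lower[d]
                    bits += 1
            total += (-1) ** bits * mvn.cdf(corner)
        return float(max(0.0, min(1.0, total)))

    def marginal_interval_prob(self, dim: int, lo: float, hi: float) -> float:
        from scipy.stats import norm as _norm

        sd = np.sqrt(self.cov[dim, dim])
        return float(
            _norm.cdf(hi, self.mean[dim], sd) - _norm.cdf(lo, self.mean[dim], sd)
        )

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.mean, self.cov, size=size)


def normal_approx(cp: ComboPosterior) -> NormalApprox:
    """Normal approximation with the combo posterior's quadrature moments."""
    if not np.all(np.isfinite(cp.sigma)):
        raise ValueError("degenerate posterior: undefined moments")
    if np.any(np.linalg.eigvalsh(np.asarray(cp.sigma)) <= 0):
        raise ValueError("degenerate posterior: covariance not positive definite")
    return NormalApprox(mean=np.asarray(cp.mu), cov=np.asarray(cp.sigma))
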