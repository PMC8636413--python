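"""Summed-score likelihood recursions for two-tier models.

Stage I accumulates, item by item, the within-cluster summed-score
likelihoods P_n(s_n | eta, xi_n) over the product grid of the primary
dimensions and one specific dimension, then integrates the specific
dimension out with rectangular quadrature to leave P_n(s_n | eta).

Stage II treats each cluster as a single polytomous "pseudo-item" with
I_n + 1 categories and convolves the cluster tables into total-score
likelihoods L(s | eta).  Omitting one focal cluster from the convolution
yields that cluster's rest-score likelihoods R_n(s_(n) | eta).

Because each table is a conditional distribution over a partition of the
response space, its values sum to one over scores at every grid node; all
accumulation is done in linear space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .model_core import QuadratureGrid, TwoTierModel, item_response, make_xi_grid

__all__ = [
    "ScoreLikelihoodTable",
    "within_cluster_likelihoods",
    "marginalize_specific",
    "combine_clusters",
    "rest_score_likelihoods",
    "total_score_likelihoods",
    "stage1_tables",
]


@dataclass
class ScoreLikelihoodTable:
    """Conditional summed-score likelihoods on a quadrature grid.

    ``values`` has shape ``(n_scores, K)`` when conditioned on eta only
    (K = number of eta product-grid nodes), or ``(n_scores, K, Q_xi)`` when
    conditioned on (eta, xi_n).
    """

    values: np.ndarray
    eta_grid: QuadratureGrid
    xi_grid: QuadratureGrid | None = None
    cluster: int | None = None

    @property
    def conditioning(self) -> Literal["eta", "eta_xi"]:
        return "eta" if self.xi_grid is None else "eta_xi"

    @property
    def n_scores(self) -> int:
        return self.values.shape[0]

    @property
    def max_score(self) -> int:
        return self.n_scores - 1

    def check(self, atol: float = 1e-10) -> None:
        """Verify the partition property: scores sum to 1 at every node."""
        totals = self.values.sum(axis=0)
        if not np.allclose(totals, 1.0, atol=atol):
            raise AssertionError("score likelihoods do not sum to 1 per node")

    def to_frame(self):
        """Scores-by-nodes DataFrame (flattening any xi axis) for export."""
        import pandas as pd

        vals = self.values.reshape(self.n_scores, -1)
        return pd.DataFrame(
            vals, index=pd.RangeIndex(self.n_scores, name="score")
        )


def _trivial_table(eta_grid: QuadratureGrid, cluster: int | None = None) -> ScoreLikelihoodTable:
    return ScoreLikelihoodTable(
        values=np.ones((1, eta_grid.size)), eta_grid=eta_grid, cluster=cluster
    )


def within_cluster_likelihoods(
    model: TwoTierModel,
    cluster: int,
    eta_grid: QuadratureGrid,
    xi_grid: QuadratureGrid | None = None,
) -> ScoreLikelihoodTable:
    """Stage-I recursion: P_n(s_n | eta, xi_n) for one item cluster.

    Initializes with the first item's response probabilities and folds the
    remaining items in one at a time; after item i the table holds i+1
    scores.  An empty cluster returns the trivial single-score table.
    Cluster 0 (items without specific loading) yields a table that is, by
    construction, constant in xi.

    The xi grid defaults to the same Q and range as one eta dimension.
    """
    items = model.cluster_items(cluster)
    if xi_grid is None:
        p = eta_grid.points[0]
        xi_grid = make_xi_grid(
            model, cluster, Q=len(p), bounds=(float(p[0]), float(p[-1]))
        )
    if not items:
        out = _trivial_table(eta_grid, cluster)
        return ScoreLikelihoodTable(
            values=np.repeat(out.values[:, :, None], xi_grid.size, axis=2),
            eta_grid=eta_grid,
            xi_grid=xi_grid,
            cluster=cluster,
        )
    K, Qx = eta_grid.size, xi_grid.size
    xi = xi_grid.points[0]
    table = np.ones((1, K, Qx))
    for it in items:
        t0, t1 = item_response(it, eta_grid.nodes[:, None, :], xi[None, :])
        t0, t1 = np.broadcast_to(t0, (K, Qx)), np.broadcast_to(t1, (K, Qx))
        new = np.zeros((table.shape[0] + 1, K, Qx))
        new[:-1] += table * t0
        new[1:] += table * t1
        table = new
    return ScoreLikelihoodTable(
        values=table, eta_grid=eta_grid, xi_grid=xi_grid, cluster=cluster
    )


def marginalize_specific(table: ScoreLikelihoodTable) -> ScoreLikelihoodTable:
    """Integrate the specific dimension out of a Stage-I table.

    P_n(s_n | eta) = sum_q P_n(s_n | eta, Y_q) W_n(Y_q), the rectangular-
    quadrature approximation with normalized prior-ordinate weights.
    """
    if table.conditioning != "eta_xi":
        raise ValueError("table is not conditioned on (eta, xi)")
    w = table.xi_grid.weights
    if len(w) != table.values.shape[2]:
        raise ValueError("xi grid weights do not match table")
    vals = table.values @ w
    return ScoreLikelihoodTable(
        values=vals, eta_grid=table.eta_grid, cluster=table.cluster
    )


def combine_clusters(
    tables: Sequence[ScoreLikelihoodTable],
) -> ScoreLikelihoodTable:
    """Stage-II convolution of eta-conditioned cluster tables.

    Each table enters as a polytomous pseudo-item; the result holds
    likelihoods for every total score 0..sum of cluster maxima.  Combining
    an empty list returns the trivial table only if impossible to infer a
    grid, so an empty input raises; the identity element is the one-score
    table {0 -> 1}.
    """
    if len(tables) == 0:
        raise ValueError("combine_clusters needs at least one table")
    for t in tables:
        if t.conditioning != "eta":
            raise ValueError("combine_clusters expects eta-conditioned tables")
        if t.eta_grid is not tables[0].eta_grid and t.eta_grid.size != tables[0].eta_grid.size:
            raise ValueError("tables must share one eta grid")
    acc = tables[0].values
    for t in tables[1:]:
        S_prev, K = acc.shape
        S_new = t.values.shape[0]
        out = np.zeros((S_prev + S_new - 1, K))
        for s_n in range(S_new):
            out[s_n : s_n + S_prev] += acc * t.values[s_n]
        acc = out
    return ScoreLikelihoodTable(values=acc, eta_grid=tables[0].eta_grid)


def stage1_tables(
    model: TwoTierModel,
    eta_grid: QuadratureGrid,
    xi_Q: int | None = None,
    xi_bounds: tuple[float, float] | None = None,
) -> dict[int, tuple[ScoreLikelihoodTable, ScoreLikelihoodTable]]:
    """Run Stage I for every nonempty cluster.

    Returns ``{cluster: (table over (eta, xi), table over eta)}``; both are
    retained because the combo posteriors need the un-marginalized table of
    the focal cluster.  The xi grid defaults to the same Q and range as one
    eta dimension.
    """
    if xi_Q is None:
        xi_Q = len(eta_grid.points[0])
    if xi_bounds is None:
        p = eta_grid.points[0]
        xi_bounds = (float(p[0]), float(p[-1]))
    out = {}
    for n in model.clusters:
        xi_grid = make_xi_grid(model, n, Q=xi_Q, bounds=xi_bounds)
        full = within_cluster_likelihoods(model, n, eta_grid, xi_grid)
        out[n] = (full, marginalize_specific(full))
    return out


def total_score_likelihoods(
    model: TwoTierModel,
    eta_grid: QuadratureGrid,
    stage1: dict[int, tuple[ScoreLikelihoodTable, ScoreLikelihoodTable]] | None = None,
) -> ScoreLikelihoodTable:
    """L(s | eta): the full Stage-II pass over all clusters."""
    if stage1 is None:
        stage1 = stage1_tables(model, eta_grid)
    return combine_clusters([marg for _, marg in stage1.values()])


def rest_score_likelihoods(
    model: TwoTierModel,
    focal: int,
    eta_grid: QuadratureGrid,
    stage1: dict[int, tuple[ScoreLikelihoodTable, ScoreLikelihoodTable]] | None = None,
) -> ScoreLikelihoodTable:
    """R_n(s_(n) | eta): Stage-II convolution omitting the focal cluster."""
    if stage1 is None:
        stage1 = stage1_tables(model, eta_grid)
    rest = [marg for n, (_, marg) in stage1.items() if n != focal]
    if not rest:
        raise ValueError("no rest items: model has no cluster besides the focal one")
    return combine_clusters(rest)
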