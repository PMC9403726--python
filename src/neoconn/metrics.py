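"""Weighted graph measures and density-sweep ("cost correction") procedure.

Conventions
-----------
* The length of an edge for shortest-path purposes is the reciprocal of
  its weight (strong connections are short), the convention of the
  standard brain-connectivity toolboxes.
* Proportional thresholding keeps the k strongest edges *with their
  weights*; degree is counted on the binarized support while strength and
  the efficiencies use the surviving weights.
* Nodal efficiency of a node is the efficiency of the subgraph induced by
  its neighbours (a per-node segregation measure); local efficiency is the
  mean of nodal efficiency over nodes; global efficiency is the mean
  inverse shortest-path length over all ordered node pairs.

Cost correction removes between-subject density confounds: each metric is
recomputed on proportionally thresholded copies of the network over a grid
of target densities (default 0.05 to 0.50 in 0.01 steps, 46 values) and
averaged across the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .io import Connectome

__all__ = [
    "default_density_grid",
    "density",
    "nodal_strength",
    "nodal_degree",
    "shortest_path_lengths",
    "global_efficiency",
    "nodal_efficiency",
    "proportional_threshold",
    "cost_corrected_features",
    "CostCorrectedMetrics",
    "features_long_table",
]


def default_density_grid() -> np.ndarray:
    """The default cost-correction grid: 0.05, 0.06, ..., 0.50 (46 densities)."""
    return np.round(np.arange(5, 51) / 100.0, 2)


def density(c: Connectome) -> float:
    """Fraction of possible node pairs connected by a positive-weight edge."""
    n = c.n_nodes
    if n < 2:
        return 0.0
    iu, ju = np.triu_indices(n, k=1)
    m = int((c.weights[iu, ju] > 0).sum())
    return 2.0 * m / (n * (n - 1))


def nodal_strength(c: Connectome) -> np.ndarray:
    """Per-node sum of incident edge weights."""
    return c.weights.sum(axis=1)


def nodal_degree(c: Connectome) -> np.ndarray:
    """Per-node count of incident positive-weight edges."""
    return (c.weights > 0).sum(axis=1)


def _length_matrix(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_path_lengths(c: Connectome) -> np.ndarray:
    """Pairwise shortest-path length matrix under the 1/weight length map.

    Unreachable pairs are ``inf``; the diagonal is 0.
    """
    return _pairwise_distances(c.weights)


def _pairwise_distances(w: np.ndarray) -> np.ndarray:
    if w.shape[0] == 0:
        return np.zeros((0, 0))
    lengths = _length_matrix(w)
    finite = np.where(np.isfinite(lengths), lengths, 0.0)
    return _csgraph_shortest_path(finite, method="D", directed=False)


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(c: Connectome) -> float:
    """Mean inverse shortest-path length over all ordered node pairs."""
    return _global_efficiency_w(c.weights)


def _global_efficiency_w(w: np.ndarray) -> float:
    return _efficiency_from_distances(_pairwise_distances(w))


def nodal_efficiency(c: Connectome) -> np.ndarray:
    """Per-node efficiency of the neighbourhood subgraph.

    For each node v, the efficiency (as in :func:`global_efficiency`) of
    the subgraph induced by v's neighbours, using the original weights
    among the neighbours; 0 when v has fewer than two neighbours.
    """
    return _nodal_efficiency_w(c.weights)


def _nodal_efficiency_w(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    adj = w > 0
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[v] = _global_efficiency_w(sub)
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def proportional_threshold(c: Connectome, target_density: float) -> Connectome:
    """Keep the k strongest edges so the density is ``target_density``.

    k = round(target × N(N−1)/2), rounding half away from zero.  Weights
    are kept, not binarized.  If the network is already at or below the
    target density the connectome is returned unchanged.  Ties in weight
    are broken by lexicographic node-pair order (stable and deterministic).
    """
    if not 0 < target_density <= 1:
        raise ValueError("target_density must be in (0, 1]")
    n = c.n_nodes
    n_pairs = n * (n - 1) // 2
    k = _round_half_away(target_density * n_pairs)
    iu, ju = np.triu_indices(n, k=1)
    wvals = c.weights[iu, ju]
    present = np.flatnonzero(wvals > 0)
    if present.size <= k:
        return c.copy()
    # stable sort: ascending (i,j) order is the tie-break after -weight
    order = present[np.argsort(-wvals[present], kind="stable")]
    keep = order[:k]
    w = np.zeros_like(c.weights)
    w[iu[keep], ju[keep]] = wvals[keep]
    w = w + w.T
    return Connectome(c.subject_id, w, list(c.node_ids))


@dataclass
class CostCorrectedMetrics:
    """Per-density and grid-averaged ("cost-corrected") network features."""

    subject_id: str
    node_ids: list[str]
    density_grid: np.ndarray
    # per-density arrays: shape (n_densities,) or (n_densities, n_nodes)
    global_efficiency: np.ndarray
    local_efficiency: np.ndarray
    mean_strength: np.ndarray
    nodal_strength: np.ndarray
    nodal_degree: np.ndarray
    nodal_efficiency: np.ndarray

    @property
    def cost_corrected(self) -> dict:
        """Arithmetic mean of each feature across the density grid."""
        return {
            "global_efficiency": float(self.global_efficiency.mean()),
            "local_efficiency": float(self.local_efficiency.mean()),
            "mean_strength": float(self.mean_strength.mean()),
            "nodal_strength": self.nodal_strength.mean(axis=0),
            "nodal_degree": self.nodal_degree.mean(axis=0),
            "nodal_efficiency": self.nodal_efficiency.mean(axis=0),
        }


def cost_corrected_features(
    c: Connectome, density_grid: np.ndarray | None = None
) -> CostCorrectedMetrics:
    """Threshold to each grid density and extract features, then average.

    The grid must be strictly increasing within (0, 1].
    """
    grid = default_density_grid() if density_grid is None else np.asarray(density_grid, float)
    if grid.size == 0:
        raise ValueError("density grid is empty")
    if (np.diff(grid) <= 0).any() or grid[0] <= 0 or grid[-1] > 1:
        raise ValueError("density grid must be strictly increasing within (0, 1]")

    n = c.n_nodes
    ge = np.empty(grid.size)
    le = np.empty(grid.size)
    ms = np.empty(grid.size)
    ns = np.empty((grid.size, n))
    nd = np.empty((grid.size, n))
    ne = np.empty((grid.size, n))
    for gi, d in enumerate(grid):
        t = proportional_threshold(c, float(d))
        ge[gi] = global_efficiency(t)
        eff = nodal_efficiency(t)
        ne[gi] = eff
        le[gi] = eff.mean()
        s = nodal_strength(t)
        ns[gi] = s
        ms[gi] = s.mean()
        nd[gi] = nodal_degree(t)
    return CostCorrectedMetrics(
        subject_id=c.subject_id,
        node_ids=list(c.node_ids),
        density_grid=grid,
        global_efficiency=ge,
        local_efficiency=le,
        mean_strength=ms,
        nodal_strength=ns,
        nodal_degree=nd,
        nodal_efficiency=ne,
    )


def features_long_table(cc: CostCorrectedMetrics, include_per_density: bool = False) -> pd.DataFrame:
    """Long-format export: subject_id, feature, node_id|global, density|cost_corrected, value."""
    rows = []
    agg = cc.cost_corrected
    for feat in ("global_efficiency", "local_efficiency", "mean_strength"):
        rows.append((cc.subject_id, feat, "global", "cost_corrected", agg[feat]))
    for feat in ("nodal_strength", "nodal_degree", "nodal_efficiency"):
        for node, val in zip(cc.node_ids, agg[feat]):
            rows.append((cc.subject_id, feat, node, "cost_corrected", float(val)))
    if include_per_density:
        for gi, d in enumerate(cc.density_grid):
            dd = f"{d:.2f}"
            rows.append((cc.subject_id, "global_efficiency", "global", dd,
                         float(cc.global_efficiency[gi])))
            rows.append((cc.subject_id, "local_efficiency", "global", dd,
                         float(cc.local_efficiency[gi])))
            rows.append((cc.subject_id, "mean_strength", "global", dd,
                         float(cc.mean_strength[gi])))
            for feat, arr in (
                ("nodal_strength", cc.nodal_strength),
                ("nodal_degree", cc.nodal_degree),
                ("nodal_efficiency", cc.nodal_efficiency),
            ):
                for node, val in zip(cc.node_ids, arr[gi]):
                    rows.append((cc.subject_id, feat, node, dd, float(val)))
    return pd.DataFrame(
        rows, columns=["subject_id", "feature", "node_id", "density", "value"]
    )
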