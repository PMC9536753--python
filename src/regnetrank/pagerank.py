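"""Personalized PageRank over the regulatory networks.

The walk runs against the direction of regulation (target gene -> regulator
TF), so a TF accumulates rank from the genes it regulates, weighted by how
differentially expressed those genes are (their node weights enter through
the personalization vector s).  The score vector solves

    v = (1 - d) s + d W v

with damping d (default 0.85), a column-stochastic walk matrix W and s the
node weights normalized to sum 1; dangling columns teleport to s.  Solved by
power iteration from v0 = s to an L1 tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from regnetrank.network import RegulatoryNetwork


@dataclass
class SolverConfig:
    damping: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise ValueError("damping must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class WalkMatrix:
    """Column-stochastic walk matrix over a fixed node ordering.

    Column j distributes mass from gene j to its regulator TFs in proportion
    to the incoming edge weights e_ij; columns of unregulated nodes are
    dangling.
    """

    nodes: list[str]
    W: sp.csr_matrix  # W[i, j]: mass flowing j -> i
    dangling: np.ndarray  # bool per column


@dataclass
class PageRankResult:
    cell_type: str
    scores: pd.Series  # indexed by node, sums to 1
    iterations: int
    residual: float


class ConvergenceError(RuntimeError):
    def __init__(self, residual: float, iterations: int):
        super().__init__(
            f"power iteration did not converge in {iterations} iterations "
            f"(last L1 residual {residual:.3e})"
        )
        self.residual = residual


def to_walk_matrix(net: RegulatoryNetwork) -> WalkMatrix:
    """Reverse the regulation direction into a column-stochastic walk."""
    nodes = sorted(net.nodes.index)
    if not nodes:
        raise ValueError("network has no nodes")
    pos = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    if len(net.edges):
        for target, group in net.edges.groupby("target", sort=True):
            total = group["weight"].sum()
            if total <= 0:
                continue  # all-zero incoming weight: stays dangling
            j = pos[target]
            for tf, w in zip(group["tf"], group["weight"]):
                rows.append(pos[tf])
                cols.append(j)
                vals.append(w / total)
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    colsum = np.asarray(W.sum(axis=0)).ravel()
    dangling = colsum == 0
    return WalkMatrix(nodes=nodes, W=W, dangling=dangling)


def personalized_pagerank(
    walk: WalkMatrix,
    s_raw: Sequence[float] | pd.Series,
    config: SolverConfig | None = None,
    cell_type: str = "",
) -> PageRankResult:
    """Power-iterate v_{t+1} = (1-d) s + d (W v_t + (dangling mass) s).

    ``s_raw`` holds positive node weights (aligned to ``walk.nodes`` if a
    Series); it is normalized to the personalization vector s internally.
    """
    config = config or SolverConfig()
    if isinstance(s_raw, pd.Series):
        s_raw = s_raw.reindex(walk.nodes).to_numpy(dtype=float)
    s_raw = np.asarray(s_raw, dtype=float)
    if s_raw.shape != (len(walk.nodes),):
        raise ValueError("node-weight vector does not match node count")
    if (s_raw <= 0).any():
        raise ValueError("node weights must be strictly positive")
    s = s_raw / s_raw.sum()

    d = config.damping
    v = s.copy()
    dangling = walk.dangling
    residual = np.inf
    for it in range(1, config.max_iter + 1):
        dangle_mass = v[dangling].sum()
        v_new = (1.0 - d) * s + d * (walk.W @ v + dangle_mass * s)
        residual = float(np.abs(v_new - v).sum())
        v = v_new
        if residual <= config.tol:
            return PageRankResult(
                cell_type=cell_type,
                scores=pd.Series(v, index=walk.nodes),
                iterations=it,
                residual=residual,
            )
    raise ConvergenceError(residual, config.max_iter)


def rank_all(
    networks: Sequence[RegulatoryNetwork],
    config: SolverConfig | None = None,
    tf_only: bool = True,
) -> pd.DataFrame:
    """One PageRank solve per cell type; returns a TF x cell-type matrix."""
    labels = [net.cell_type for net in networks]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate cell-type labels")
    columns: dict[str, pd.Series] = {}
    tf_index: pd.Index | None = None
    for net in networks:
        walk = to_walk_matrix(net)
        weights = net.nodes["node_weight"]
        try:
            res = personalized_pagerank(walk, weights, config, cell_type=net.cell_type)
        except ConvergenceError as exc:
            raise RuntimeError(f"PageRank failed for cell type {net.cell_type}") from exc
        scores = res.scores
        if tf_only:
            tfs = sorted(net.nodes.index[net.nodes["is_tf"]])
            scores = scores.loc[tfs]
        if tf_index is None:
            tf_index = scores.index
        elif not tf_index.equals(scores.index):
            raise ValueError("networks do not share a TF namespace")
        columns[net.cell_type] = scores
    matrix = pd.DataFrame(columns)
    matrix.index.name = "tf"
    return matrix
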