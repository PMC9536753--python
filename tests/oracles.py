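"""Independent reference implementations used to check the package.

These deliberately avoid the code paths they verify: the PageRank oracle is
a dense linear solve, the motif oracle enumerates every k-mer, and the
Fisher oracle sums hypergeometric terms with exact integer combinatorics.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd

from regnetrank.motifs import ScoreModel
from regnetrank.network import RegulatoryNetwork
from regnetrank.pagerank import WalkMatrix


def dense_pagerank(walk: WalkMatrix, s_raw: np.ndarray, damping: float) -> np.ndarray:
    """Solve (I - d W') v = (1 - d) s directly, where W' is the walk matrix
    with dangling columns replaced by the personalization vector s."""
    s = np.asarray(s_raw, dtype=float)
    s = s / s.sum()
    W = walk.W.toarray()
    Wp = W.copy()
    Wp[:, walk.dangling] = s[:, None]
    n = len(s)
    v = np.linalg.solve(np.eye(n) - damping * Wp, (1.0 - damping) * s)
    return v


def enumerate_pvalues(model: ScoreModel) -> dict[int, float]:
    """Exhaustive k-mer enumeration of P(score >= s) under the background.

    Only feasible for motif lengths <= ~6 (4^L sequences)."""
    L = model.length
    bg = model.background
    by_score: dict[int, float] = {}
    for kmer in itertools.product(range(4), repeat=L):
        score = int(sum(model.logodds_int[i, b] for i, b in enumerate(kmer)))
        prob = float(np.prod([bg[b] for b in kmer]))
        by_score[score] = by_score.get(score, 0.0) + prob
    scores = sorted(by_score, reverse=True)
    sf: dict[int, float] = {}
    acc = 0.0
    for sc in scores:
        acc += by_score[sc]
        sf[sc] = acc
    return sf


def fisher_two_sided(n_ab: int, n_a: int, n_b: int, rest: int) -> float:
    """Two-sided Fisher p by enumerating all tables with fixed margins and
    summing probabilities <= that of the observed table."""
    row1 = n_ab + n_a
    col1 = n_ab + n_b
    total = n_ab + n_a + n_b + rest

    def table_prob(k: int) -> float:
        return (
            comb(col1, k) * comb(total - col1, row1 - k) / comb(total, row1)
        )

    p_obs = table_prob(n_ab)
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    return sum(
        p for k in range(lo, hi + 1) if (p := table_prob(k)) <= p_obs * (1 + 1e-12)
    )


def random_regulatory_network(
    rng: np.random.Generator, n_nodes: int, cell_type: str = "ct"
) -> RegulatoryNetwork:
    """A random weighted TF->gene network for solver stress tests."""
    n_tfs = max(1, n_nodes // 4)
    genes = [f"g{i}" for i in range(n_nodes)]
    is_tf = np.zeros(n_nodes, dtype=bool)
    is_tf[:n_tfs] = True
    nodes = pd.DataFrame(
        {"is_tf": is_tf, "node_weight": rng.uniform(0.1, 5.0, size=n_nodes)},
        index=pd.Index(genes, name="gene"),
    )
    rows = []
    for ti in range(n_tfs):
        targets = rng.choice(n_nodes, size=rng.integers(0, max(2, n_nodes // 2)), replace=False)
        for gj in targets:
            rows.append((genes[ti], genes[gj], float(rng.uniform(0.01, 3.0)), 1))
    edges = pd.DataFrame(rows, columns=["tf", "target", "weight", "n_sites"])
    return RegulatoryNetwork(cell_type=cell_type, nodes=nodes, edges=edges)


def welch_reference(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch's t-test from first principles: Welch-Satterthwaite df and a
    direct special-function evaluation of the t CDF."""
    from scipy.special import stdtr

    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = vx / nx + vy / ny
    t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
    df = se2**2 / (vx**2 / (nx**2 * (nx - 1)) + vy**2 / (ny**2 * (ny - 1)))
    p = 2.0 * stdtr(df, -abs(t))
    return float(t), float(p)
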