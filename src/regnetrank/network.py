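"""Assembly of per-cell-type weighted TF regulatory networks.

Node weights are e^z, where z is the gene's expression z-score across cell
types (computed on log2(x+1)-transformed values by default, sample sd).
Edge weights follow e_ij = g * sum_k p_k * m_k where g is the TF's
expression, p_k the sigmoid-rescaled peak intensity of site k and m_k the
sigmoid-rescaled motif affinity (-log10 of the exact match p-value).  Sites
are linked to genes through a strand-aware promoter window, optionally
augmented by an enhancer -> gene link table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from regnetrank.io import ExpressionMatrix, GeneAnnotation
from regnetrank.motifs import BindingSite

logger = logging.getLogger(__name__)

SIGMOID_MIDPOINT = 5.0
MOTIF_NEG_LOG10_CAP = 20.0  # match p = 0 saturates far beyond the sigmoid knee


def zscore_expression(expr: ExpressionMatrix, log_transform: bool = True) -> pd.DataFrame:
    """Per-gene z-scores across cell types (sample sd, n-1 denominator).

    Zero-variance genes get z = 0 in every cell type.
    """
    if len(expr.cell_types) < 2:
        raise ValueError("z-scores require at least 2 cell types")
    x = expr.data.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=expr.data.index, columns=expr.data.columns)


def node_weight(z: float | np.ndarray) -> float | np.ndarray:
    """Node weight e^z of a gene with expression z-score z."""
    return np.exp(z)


def sigmoid_rescale(x: float | np.ndarray, midpoint: float = SIGMOID_MIDPOINT):
    """Rescale a -log10(p) intensity to (0, 1) via 1 / (1 + e^-(x - midpoint))."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - midpoint)))


@dataclass
class LinkageRule:
    """How binding sites are linked to target genes.

    A site is assigned to a gene when it overlaps the gene's strand-aware
    promoter window (``upstream`` bp before to ``downstream`` bp after the
    TSS), or when it overlaps an interval in the optional enhancer link
    table ``links`` (rows of (contig, start, end, gene)).
    """

    upstream: int = 5000
    downstream: int = 1000
    links: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("promoter window extents must be >= 0")

    def promoter_window(self, tss: int, strand: str) -> tuple[int, int]:
        if strand == "+":
            return tss - self.upstream, tss + self.downstream + 1
        return tss - self.downstream, tss + self.upstream + 1


def assign_sites(
    sites: Sequence[BindingSite],
    annotation: GeneAnnotation,
    rule: LinkageRule | None = None,
) -> dict[str, list[BindingSite]]:
    """Map each binding site to the genes whose promoter window (or linked
    enhancer) it overlaps.  A site may serve multiple genes; sites assigned
    to no gene are dropped (count logged)."""
    rule = rule or LinkageRule()
    if rule.links:
        known = set(annotation.genes)
        for _, _, _, gene in rule.links:
            if gene not in known:
                raise ValueError(f"enhancer link targets unknown gene {gene!r}")
    trees: dict[str, IntervalTree] = {}
    for sym, row in annotation.table.iterrows():
        lo, hi = rule.promoter_window(int(row["tss"]), row["strand"])
        trees.setdefault(row["contig"], IntervalTree()).addi(lo, hi, sym)
    for contig, start, end, gene in rule.links:
        trees.setdefault(contig, IntervalTree()).addi(start, end, gene)

    assigned: dict[str, list[BindingSite]] = {}
    n_dropped = 0
    for site in sites:
        tree = trees.get(site.contig)
        hits = tree.overlap(site.start, site.end) if tree is not None else ()
        if not hits:
            n_dropped += 1
            continue
        for iv in hits:
            assigned.setdefault(iv.data, []).append(site)
    if n_dropped:
        logger.info("%d sites fell outside every promoter window / link", n_dropped)
    for lst in assigned.values():
        lst.sort(key=lambda s: (s.contig, s.start, s.motif_id, s.strand))
    return assigned


def edge_weight(
    g: float,
    sites: Sequence[BindingSite],
    motif_midpoint: float = SIGMOID_MIDPOINT,
    peak_midpoint: float = SIGMOID_MIDPOINT,
) -> float:
    """Edge weight g * sum_k p_k * m_k over the sites linking a TF to a gene.

    p_k is the sigmoid-rescaled ATAC peak intensity; m_k the sigmoid-rescaled
    -log10 motif match p-value (capped so a perfect match stays finite).
    """
    if g < 0:
        raise ValueError("TF expression g must be >= 0")
    total = 0.0
    for s in sites:
        with np.errstate(divide="ignore"):
            neg_log10_m = -np.log10(s.pvalue) if s.pvalue > 0 else np.inf
        neg_log10_m = min(neg_log10_m, MOTIF_NEG_LOG10_CAP)
        p_term = float(sigmoid_rescale(s.peak_neg_log10_p, peak_midpoint))
        m_term = float(sigmoid_rescale(neg_log10_m, motif_midpoint))
        total += p_term * m_term
    return g * total


@dataclass
class RegulatoryNetwork:
    """A weighted directed TF -> gene network for one cell type.

    ``nodes`` is indexed by gene symbol with columns is_tf and node_weight;
    ``edges`` has columns tf, target, weight, n_sites.  ``edge_sites`` keeps
    the contributing sites per (tf, target) so weights stay recomputable.
    """

    cell_type: str
    nodes: pd.DataFrame
    edges: pd.DataFrame
    edge_sites: dict[tuple[str, str], list[BindingSite]] = field(default_factory=dict)
    tf_expression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.nodes["node_weight"] <= 0).any():
            raise ValueError("node weights must be positive")
        if len(self.edges):
            bad = ~self.edges["tf"].isin(self.nodes.index[self.nodes["is_tf"]])
            if bad.any():
                raise ValueError("every edge source must be a TF node")

    def audit_weights(self, tol: float = 1e-9) -> bool:
        """Recompute every edge weight from its stored sites and g."""
        for row in self.edges.itertuples(index=False):
            sites = self.edge_sites.get((row.tf, row.target))
            if sites is None:
                return False
            w = edge_weight(self.tf_expression[row.tf], sites)
            if abs(w - row.weight) > tol:
                return False
        return True


def build_network(
    cell_type: str,
    sites: Sequence[BindingSite],
    annotation: GeneAnnotation,
    expr: ExpressionMatrix,
    rule: LinkageRule | None = None,
    log_transform: bool = True,
    keep_sites: bool = True,
) -> RegulatoryNetwork:
    """Assemble the weighted regulatory network of one cell type.

    Nodes are all genes in the expression matrix; node weights are e^z for
    this cell type.  One edge is created per (TF, gene) pair with at least
    one assigned site of one of the TF's motifs; TFs sharing a motif each
    get their own edges, scaled by their own expression g.
    """
    if cell_type not in expr.cell_types:
        raise ValueError(f"cell type {cell_type!r} absent from expression matrix")
    z = zscore_expression(expr, log_transform=log_transform)[cell_type]
    genes = expr.genes
    raw = expr.data[cell_type]
    g_of = np.log2(raw + 1.0) if log_transform else raw.astype(float)

    is_tf = annotation.table["is_tf"].reindex(genes, fill_value=False)
    nodes = pd.DataFrame(
        {"is_tf": is_tf.to_numpy(), "node_weight": node_weight(z.to_numpy())},
        index=pd.Index(genes, name="gene"),
    )

    gene_sites = assign_sites(sites, annotation, rule)
    gene_set = set(genes)
    pair_sites: dict[tuple[str, str], list[BindingSite]] = {}
    skipped_tfs: set[str] = set()
    for gene, slist in gene_sites.items():
        if gene not in gene_set:
            continue
        for site in slist:
            for tf in site.tfs:
                if tf not in gene_set:
                    skipped_tfs.add(tf)
                    continue
                pair_sites.setdefault((tf, gene), []).append(site)
    for tf in sorted(skipped_tfs):
        logger.warning("TF %s in motif map has no expression; skipped", tf)

    rows = []
    for (tf, gene), slist in sorted(pair_sites.items()):
        w = edge_weight(float(g_of[tf]), slist)
        rows.append((tf, gene, w, len(slist)))
    edges = pd.DataFrame(rows, columns=["tf", "target", "weight", "n_sites"])
    if not len(rows):
        logger.warning("cell type %s: no binding sites passed; network has no edges", cell_type)
    net = RegulatoryNetwork(
        cell_type=cell_type,
        nodes=nodes,
        edges=edges,
        edge_sites=pair_sites if keep_sites else {},
        tf_expression={tf: float(g_of[tf]) for tf in {t for t, _ in pair_sites}},
    )
    return net


def write_network(net: RegulatoryNetwork, edges_path, nodes_path) -> None:
    out = net.edges.copy()
    out.insert(0, "cell_type", net.cell_type)
    out.to_csv(edges_path, sep="\t", index=False, float_format="%.12g")
    net.nodes.to_csv(nodes_path, sep="\t", float_format="%.12g", index_label="gene")


def read_network(cell_type: str, edges_path, nodes_path) -> RegulatoryNetwork:
    edges = pd.read_csv(edges_path, sep="\t")
    if len(edges):
        edges = edges.drop(columns=["cell_type"])
    else:
        edges = pd.DataFrame(columns=["tf", "target", "weight", "n_sites"])
    nodes = pd.read_csv(nodes_path, sep="\t", index_col="gene")
    return RegulatoryNetwork(cell_type=cell_type, nodes=nodes, edges=edges)


def subsample_for_visualization(
    net: RegulatoryNetwork,
    focal_tf: str,
    min_weight: float = 1.0,
    n_regulatees: int = 500,
    edge_fraction: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Subsample a focal TF's neighbourhood for display.

    Edges below ``min_weight`` are removed; up to ``n_regulatees`` regulatees
    are sampled keeping the TF : non-TF ratio constant; edges among the
    sampled regulatees are added; finally ``edge_fraction`` of all edges is
    kept.  Deterministic under ``seed``.
    """
    if focal_tf not in net.nodes.index:
        raise ValueError(f"{focal_tf!r} is not a node")
    rng = np.random.default_rng(seed)
    strong = net.edges[net.edges["weight"] >= min_weight]
    regulatees = sorted(strong.loc[strong["tf"] == focal_tf, "target"])
    if not regulatees:
        logger.warning("focal TF %s has no regulatees above min_weight", focal_tf)
        return pd.DataFrame(columns=["tf", "target", "weight"])
    is_tf = net.nodes["is_tf"]
    tf_reg = [g for g in regulatees if is_tf.get(g, False)]
    non_reg = [g for g in regulatees if not is_tf.get(g, False)]
    if len(regulatees) > n_regulatees:
        frac = n_regulatees / len(regulatees)
        n_tf = int(round(len(tf_reg) * frac))
        n_non = n_regulatees - n_tf
        tf_reg = sorted(rng.choice(tf_reg, size=min(n_tf, len(tf_reg)), replace=False))
        non_reg = sorted(rng.choice(non_reg, size=min(n_non, len(non_reg)), replace=False))
    sampled = set(tf_reg) | set(non_reg)
    keep = strong[
        ((strong["tf"] == focal_tf) & strong["target"].isin(sampled))
        | (strong["tf"].isin(sampled) & strong["target"].isin(sampled))
    ][["tf", "target", "weight"]].reset_index(drop=True)
    n_keep = int(round(len(keep) * edge_fraction))
    idx = np.sort(rng.choice(len(keep), size=n_keep, replace=False))
    return keep.iloc[idx].reset_index(drop=True)
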