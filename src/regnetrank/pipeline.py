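"""End-to-end orchestration: scan -> build-network -> rank -> specificity
-> cluster, with every stage consuming its inputs from disk so a run can be
restarted at any stage.  A JSON-lines log records per-stage counts, and the
run configuration (plus its hash) is serialized into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from regnetrank import io as gio
from regnetrank import motifs as gm
from regnetrank import network as gn
from regnetrank import pagerank as gp
from regnetrank import specificity as gs
from regnetrank import clustering as gc


@dataclass
class RunConfig:
    """All inputs and stage parameters of one pipeline run."""

    genome: str
    peaks_dir: str
    expression: str
    annotation: str
    motifs: str
    tf_map: str
    outdir: str
    motif_p: float = 1e-5
    promoter_up: int = 5000
    promoter_down: int = 1000
    damping: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000
    tier: str = "lineage"
    groups: dict[str, list[str]] = field(default_factory=dict)
    k_range: list[int] = field(default_factory=lambda: list(range(2, 13)))
    metrics: list[str] = field(default_factory=lambda: list(gc.METRICS))
    restarts: int = 10
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        for key in ("genome", "peaks_dir", "expression", "annotation", "motifs", "tf_map"):
            if not Path(getattr(self, key)).exists():
                raise FileNotFoundError(f"config input {key} = {getattr(self, key)!r} missing")
        if self.tier not in gs.CUTOFF_TIERS:
            raise ValueError(f"unknown cutoff tier {self.tier!r}")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class _StageLog:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.config_hash = config_hash

    def record(self, stage: str, **counts) -> None:
        entry = {"stage": stage, "config": self.config_hash, "time": time.time(), **counts}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _cell_types(config: RunConfig) -> list[str]:
    return sorted(p.stem for p in Path(config.peaks_dir).glob("*.narrowPeak"))


def stage_scan(config: RunConfig, log: _StageLog | None = None) -> Path:
    """Scan each cell type's peaks for motif matches; writes sites/<ct>.bed."""
    out = Path(config.outdir) / "sites"
    out.mkdir(parents=True, exist_ok=True)
    genome = gio.read_fasta(config.genome)
    library = gio.read_motifs_meme(config.motifs, config.tf_map)
    background = gm.genome_background(genome)
    models = gm.build_models(library, background)
    total = 0
    for ct in _cell_types(config):
        peaks = gio.read_narrowpeak(Path(config.peaks_dir) / f"{ct}.narrowPeak")
        sites = gm.scan_peaks(genome, peaks, models, p_threshold=config.motif_p)
        gm.write_sites_bed(sites, out / f"{ct}.bed")
        total += len(sites)
    if log:
        log.record("scan", n_sites=total, n_cell_types=len(_cell_types(config)))
    return out


def stage_build_network(config: RunConfig, log: _StageLog | None = None) -> Path:
    """Assemble one weighted network per cell type from the scanned sites."""
    out = Path(config.outdir) / "networks"
    out.mkdir(parents=True, exist_ok=True)
    library = gio.read_motifs_meme(config.motifs, config.tf_map)
    annotation = gio.read_bed_annotation(config.annotation, tf_symbols=library.tf_symbols())
    expr = gio.read_expression(config.expression)
    rule = gn.LinkageRule(upstream=config.promoter_up, downstream=config.promoter_down)
    sites_dir = Path(config.outdir) / "sites"
    n_edges = 0
    for ct in _cell_types(config):
        sites = gm.read_sites_bed(sites_dir / f"{ct}.bed", library)
        net = gn.build_network(ct, sites, annotation, expr, rule, keep_sites=False)
        gn.write_network(net, out / f"{ct}.edges.tsv", out / f"{ct}.nodes.tsv")
        n_edges += len(net.edges)
    if log:
        log.record("build_network", n_edges=n_edges)
    return out

def stage_rank(config: RunConfig, log: _StageLog | None = None) -> Path:
    """Personalized PageRank per cell type; writes pagerank.tsv."""
    nets_dir = Path(config.outdir) / "networks"
    networks = [
        gn.read_network(ct, nets_dir / f"{ct}.edges.tsv", nets_dir / f"{ct}.nodes.tsv")
        for ct in _cell_types(config)
    ]
    solver = gp.SolverConfig(damping=config.damping, tol=config.tol, max_iter=config.max_iter)
    matrix = gp.rank_all(networks, solver)
    out = Path(config.outdir) / "pagerank.tsv"
    gio.write_pagerank_matrix(matrix, out)
    if log:
        log.record("rank", n_tfs=matrix.shape[0], n_cell_types=matrix.shape[1])
    return out


def _default_groups(columns: list[str]) -> dict[str, list[str]]:
    """Group cell types by label prefix before the first '_' (the lineage)."""
    groups: dict[str, list[str]] = {}
    for c in columns:
        groups.setdefault(c.split("_")[0], []).append(c)
    return {k: sorted(v) for k, v in sorted(groups.items())}


def stage_specificity(config: RunConfig, log: _StageLog | None = None) -> Path:
    """Per-lineage specific-TF calls at the configured cutoff tier."""
    matrix = gio.read_pagerank_matrix(Path(config.outdir) / "pagerank.tsv")
    groups = config.groups or _default_groups(list(matrix.columns))
    p_cut, lfc_cut = gs.CUTOFF_TIERS[config.tier]
    out = Path(config.outdir) / "specificity"
    out.mkdir(parents=True, exist_ok=True)
    n_passed = 0
    all_cols = set(matrix.columns)
    for label, cts in groups.items():
        design = gs.GroupDesign(
            target=set(cts), background=all_cols - set(cts), label=label
        )
        calls = gs.specific_tfs(matrix, design, p_cut, lfc_cut)
        calls.to_csv(out / f"{label}.tsv", sep="\t", float_format="%.12g")
        n_passed += int(calls["passed"].sum())
    active = gs.find_active_tfs(matrix)
    pd.Series(active, name="tf").to_csv(out / "active_tfs.tsv", sep="\t", index=False)
    if log:
        log.record("specificity", n_passed=n_passed, n_active=len(active))
    return out


def stage_cluster(config: RunConfig, log: _StageLog | None = None) -> Path:
    """Transcriptional-wave clustering of z-normalized PageRank profiles."""
    matrix = gio.read_pagerank_matrix(Path(config.outdir) / "pagerank.tsv")
    z = gs.znormalize_rows(matrix)
    cfg = gc.ClusteringConfig(
        metrics=tuple(config.metrics),
        k_range=tuple(k for k in config.k_range if k < len(z)),
        restarts=config.restarts,
        seed=config.seed,
    )
    reduced, _ = gc.pca_reduce(z, cfg)
    waves = gc.silhouette_select(reduced, cfg)
    out = Path(config.outdir) / "clusters"
    out.mkdir(parents=True, exist_ok=True)
    waves.labels.to_csv(out / "assignments.tsv", sep="\t", index_label="tf")
    waves.silhouette_grid.to_csv(out / "silhouette_grid.tsv", sep="\t", float_format="%.12g")
    profiles = matrix.groupby(waves.labels).mean()
    profiles.to_csv(out / "cluster_profiles.tsv", sep="\t", float_format="%.12g", index_label="cluster")
    with open(out / "selection.json", "w") as fh:
        json.dump({"metric": waves.metric, "k": int(waves.k)}, fh, sort_keys=True)
    if log:
        log.record("cluster", metric=waves.metric, k=int(waves.k))
    return out


STAGES = {
    "scan": stage_scan,
    "build_network": stage_build_network,
    "rank": stage_rank,
    "specificity": stage_specificity,
    "cluster": stage_cluster,
}


def run_all(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the pipeline stages in order; each stage reads its inputs from
    disk, so a partial output directory can be resumed stage-wise."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")
    log = _StageLog(outdir / "log.jsonl", config.config_hash())
    for name in stages or list(STAGES):
        try:
            STAGES[name](config, log)
        except Exception as exc:
            raise RuntimeError(
                f"stage {name!r} failed (config {config.config_hash()}): {exc}"
            ) from exc
    return outdir
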