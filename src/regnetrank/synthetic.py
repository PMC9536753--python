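"""Synthetic multi-lineage datasets with planted ground truth.

The generator emulates the structure of an immune-compendium input: a panel
of cell lineages each with several cell types, matched per-cell-type ATAC
peak sets and a gene x cell-type expression matrix, a genome in which
high-information motif instances are planted inside the open promoters of
lineage-upregulated genes, and log-normally distributed expression.  TF
roles are planted:

    lineage_driver   — motif instances in its lineage's module-gene
                       promoters (open only in that lineage) and expression
                       up in that lineage;
    constitutive     — motifs in many housekeeping promoters (open
                       everywhere) and high expression everywhere;
    memory_driver    — motifs in housekeeping promoters, expression up in
                       the designated "memory" cell types;
    neutral          — motifs sparsely planted in housekeeping promoters,
                       flat expression.

Everything is a pure function of (design, seed): re-emission is
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from regnetrank.io import (
    ExpressionMatrix,
    GeneAnnotation,
    GenomeSequence,
    MotifLibrary,
    MotifPWM,
    Peak,
    PeakSet,
    write_bed_annotation,
    write_expression,
    write_fasta,
    write_motifs_meme,
    write_narrowpeak,
    write_tf_map,
)
from regnetrank.motifs import build_score_model, scan_peaks

CONTIG_LEN = 3000
TSS_POS = 2500
PEAK_START, PEAK_END = 2100, 2500  # ~400 bp promoter peak upstream of the TSS
BG_PEAK_START, BG_PEAK_END = 200, 700
SLOT0, SLOT_STEP = 2150, 14  # planted-site slots inside the promoter peak
N_SLOTS = 24


@dataclass
class SyntheticDesign:
    """The planted study design: lineage panel, TF roles, effect sizes."""

    n_lineages: int = 5
    cells_per_lineage: int = 4
    n_tfs: int = 50
    n_genes: int = 300
    drivers_per_lineage: int = 3
    n_constitutive: int = 5
    n_memory: int = 3
    motif_length: int = 12
    sites_per_promoter: int = 2  # per (driver, module-gene promoter)
    effect_log2fc: float = 3.0  # lineage up-regulation of module genes/drivers
    memory_effect_log2fc: float = 1.5  # smaller shift for memory drivers
    noise_sd: float = 0.25  # sd of log2 expression noise
    contaminate: bool = False  # heavy-tail contamination of expression noise
    seed: int = 0
    # derived assignments (filled by make_design)
    lineages: dict[str, list[str]] = field(default_factory=dict)
    tf_roles: dict[str, str] = field(default_factory=dict)
    gene_module: dict[str, str] = field(default_factory=dict)
    memory_cell_types: list[str] = field(default_factory=list)

    @property
    def cell_types(self) -> list[str]:
        return [ct for cts in self.lineages.values() for ct in cts]

    @property
    def tf_symbols(self) -> list[str]:
        return sorted(self.tf_roles)

    @property
    def gene_symbols(self) -> list[str]:
        return sorted(self.gene_module)

    def drivers_of(self, lineage: str) -> list[str]:
        return sorted(
            tf for tf, role in self.tf_roles.items() if role == f"lineage_driver:{lineage}"
        )

    def lineage_of_cell_type(self, ct: str) -> str:
        for lin, cts in self.lineages.items():
            if ct in cts:
                return lin
        raise KeyError(ct)


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery."""

    tf_roles: dict[str, str]
    gene_module: dict[str, str]
    memory_cell_types: list[str]
    planted_sites: list[dict]  # contig, start, end, strand, motif_id

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def make_design(
    n_lineages: int = 5,
    cells_per_lineage: int = 4,
    n_tfs: int = 50,
    n_genes: int = 300,
    drivers_per_lineage: int = 3,
    n_constitutive: int = 5,
    n_memory: int = 3,
    effect_log2fc: float = 3.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    **kwargs,
) -> SyntheticDesign:
    """Build the desk-scale study design (defaults: 5 lineages x 4 cell
    types, 50 TFs with 3 drivers per lineage and 5 constitutive, 300 genes).
    Deterministic under ``seed``."""
    if n_lineages < 1 or cells_per_lineage < 1:
        raise ValueError("need at least one lineage and one cell type per lineage")
    n_special = n_lineages * drivers_per_lineage + n_constitutive + n_memory
    if n_tfs < n_special:
        raise ValueError(f"n_tfs={n_tfs} cannot host {n_special} special roles")
    design = SyntheticDesign(
        n_lineages=n_lineages,
        cells_per_lineage=cells_per_lineage,
        n_tfs=n_tfs,
        n_genes=n_genes,
        drivers_per_lineage=drivers_per_lineage,
        n_constitutive=n_constitutive,
        n_memory=n_memory,
        effect_log2fc=effect_log2fc,
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )
    lineage_names = [f"L{i+1}" for i in range(n_lineages)]
    design.lineages = {
        lin: [f"{lin}_ct{j+1}" for j in range(cells_per_lineage)] for lin in lineage_names
    }
    # memory group: the last cell type of the first n_memory-compatible lineages
    design.memory_cell_types = [
        design.lineages[lin][-1] for lin in lineage_names[: min(3, n_lineages)]
    ]
    tfs = [f"TF{i+1:03d}" for i in range(n_tfs)]
    roles: dict[str, str] = {}
    i = 0
    for lin in lineage_names:
        for _ in range(drivers_per_lineage):
            roles[tfs[i]] = f"lineage_driver:{lin}"
            i += 1
    for _ in range(n_constitutive):
        roles[tfs[i]] = "constitutive"
        i += 1
    for _ in range(n_memory):
        roles[tfs[i]] = "memory_driver"
        i += 1
    for j in range(i, n_tfs):
        roles[tfs[j]] = "neutral"
    design.tf_roles = roles
    # genes: two thirds split across lineage modules, rest housekeeping
    genes = [f"G{i+1:04d}" for i in range(n_genes)]
    n_module_total = (2 * n_genes) // 3
    per_lineage = n_module_total // n_lineages
    module: dict[str, str] = {}
    i = 0
    for lin in lineage_names:
        for _ in range(per_lineage):
            module[genes[i]] = lin
            i += 1
    for j in range(i, n_genes):
        module[genes[j]] = "housekeeping"
    design.gene_module = module
    return design


# ---------------------------------------------------------------------------
# Genome + motifs
# ---------------------------------------------------------------------------


def _random_consensus(rng: np.random.Generator, length: int, existing: list[str]) -> str:
    """Draw a consensus k-mer at Hamming distance >= length//3 from all
    previous ones, so planted motifs stay mutually dissimilar."""
    min_dist = max(2, length // 3)
    for _ in range(10_000):
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if all(
            sum(a != b for a, b in zip(cand, prev)) >= min_dist for prev in existing
        ):
            return cand
    raise RuntimeError("could not draw a dissimilar consensus")


def _consensus_pwm(consensus: str, dominant: float = 0.97) -> np.ndarray:
    pwm = np.full((len(consensus), 4), (1 - dominant) / 3)
    for i, base in enumerate(consensus):
        pwm[i, "ACGT".index(base)] = dominant
    return pwm


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def _planting_plan(design: SyntheticDesign) -> dict[str, list[tuple[str, str]]]:
    """Per gene: list of (tf, motif instance kind) plantings.

    Driver motifs go into their lineage's module-gene promoters; the other
    roles are planted into housekeeping promoters at role-specific density.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 11]))
    hk = sorted(g for g, m in design.gene_module.items() if m == "housekeeping")
    plan: dict[str, list[tuple[str, str]]] = {g: [] for g in design.gene_symbols}
    for gene, mod in sorted(design.gene_module.items()):
        if mod == "housekeeping":
            continue
        for tf in design.drivers_of(mod):
            for _ in range(design.sites_per_promoter):
                plan[gene].append((tf, "driver"))
    density = {"constitutive": (100, 1), "memory_driver": (20, 2), "neutral": (10, 1)}
    for tf in design.tf_symbols:
        role = design.tf_roles[tf].split(":")[0]
        if role not in density:
            continue
        n_prom, n_sites = density[role]
        n_prom = min(n_prom, len(hk))
        chosen = rng.choice(hk, size=n_prom, replace=False)
        for gene in sorted(chosen):
            for _ in range(n_sites):
                plan[gene].append((tf, role))
    return plan


def generate_genome_and_motifs(
    design: SyntheticDesign,
) -> tuple[GenomeSequence, MotifLibrary, GeneAnnotation, GroundTruth]:
    """One contig per gene (TF genes included) with a promoter region;
    mutually dissimilar high-information PWMs, one per TF; motif instances
    planted at recorded promoter positions."""
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 7]))
    consensi: list[str] = []
    motifs = []
    for tf in design.tf_symbols:
        cons = _random_consensus(rng, design.motif_length, consensi)
        consensi.append(cons)
        motifs.append(
            MotifPWM(motif_id=f"M_{tf}", tfs=[tf], matrix=_consensus_pwm(cons))
        )
    library = MotifLibrary(motifs)
    cons_of = dict(zip(design.tf_symbols, consensi))

    plan = _planting_plan(design)
    contigs: dict[str, str] = {}
    planted: list[dict] = []
    all_syms = design.gene_symbols + design.tf_symbols
    for sym in all_syms:
        seq = rng.integers(0, 4, size=CONTIG_LEN)
        chars = np.array(list("ACGT"))[seq]
        plantings = plan.get(sym, [])
        if plantings:
            if len(plantings) > N_SLOTS:
                raise ValueError(f"too many plantings for promoter of {sym}")
            slots = rng.choice(N_SLOTS, size=len(plantings), replace=False)
            for (tf, _kind), slot in zip(plantings, slots):
                start = SLOT0 + SLOT_STEP * int(slot)
                instance = cons_of[tf]
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    instance = _revcomp(instance)
                chars[start : start + design.motif_length] = list(instance)
                planted.append(
                    {
                        "contig": f"chr_{sym}",
                        "start": start,
                        "end": start + design.motif_length,
                        "strand": strand,
                        "motif_id": f"M_{tf}",
                    }
                )
        contigs[f"chr_{sym}"] = "".join(chars)
    genome = GenomeSequence(contigs)
    ann_table = pd.DataFrame(
        {
            "contig": [f"chr_{sym}" for sym in all_syms],
            "tss": TSS_POS,
            "strand": "+",
        },
        index=pd.Index(all_syms, name="symbol"),
    )
    annotation = GeneAnnotation(ann_table)
    annotation.flag_tfs(design.tf_symbols)
    truth = GroundTruth(
        tf_roles=dict(design.tf_roles),
        gene_module=dict(design.gene_module),
        memory_cell_types=list(design.memory_cell_types),
        planted_sites=sorted(
            planted, key=lambda s: (s["contig"], s["start"], s["motif_id"])
        ),
    )
    return genome, library, annotation, truth


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------


def open_genes(design: SyntheticDesign, cell_type: str) -> list[str]:
    """Genes whose promoter is open in ``cell_type``: housekeeping promoters
    everywhere, module promoters only in their own lineage.  TF promoters
    stay closed — regulation of TFs themselves is not part of the planted
    design, so leaving them closed keeps the ground truth exact."""
    lin = design.lineage_of_cell_type(cell_type)
    return sorted(
        g for g, mod in design.gene_module.items() if mod in ("housekeeping", lin)
    )


def generate_peaks(design: SyntheticDesign, cell_type: str) -> PeakSet:
    """Promoter peaks for the cell type's open genes (-log10 p ~ U(4, 10))
    plus low-signal background peaks away from any planted site."""
    ct_index = design.cell_types.index(cell_type)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 23, ct_index]))
    records = []
    for sym in open_genes(design, cell_type):
        records.append(
            Peak(f"chr_{sym}", PEAK_START, PEAK_END, float(rng.uniform(4, 10)))
        )
    hk = sorted(g for g, m in design.gene_module.items() if m == "housekeeping")
    n_bg = max(1, len(hk) // 5)
    for sym in rng.choice(hk, size=n_bg, replace=False):
        records.append(
            Peak(f"chr_{sym}", BG_PEAK_START, BG_PEAK_END, float(rng.uniform(1, 4)))
        )
    return PeakSet(records)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(design: SyntheticDesign) -> ExpressionMatrix:
    """Log-normal expression: log2 value = baseline + lineage effect + noise.

    Module genes and lineage drivers gain ``effect_log2fc`` in their own
    lineage; constitutive drivers are high everywhere; memory drivers gain
    the effect in the memory cell types.  With ``contaminate`` a 10% mixture
    of 4x-sd noise makes rows heavy-tailed (for testing the normality gate).
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 31]))
    cts = design.cell_types
    lin_of = {ct: design.lineage_of_cell_type(ct) for ct in cts}
    rows = {}
    all_syms = design.gene_symbols + design.tf_symbols

    def noise(n: int) -> np.ndarray:
        eps = rng.normal(0.0, design.noise_sd, size=n)
        if design.contaminate:
            mask = rng.random(n) < 0.1
            eps[mask] = rng.normal(0.0, 4 * design.noise_sd, size=int(mask.sum()))
        return eps

    for sym in all_syms:
        if sym in design.gene_module:
            mod = design.gene_module[sym]
            if mod == "housekeeping":
                base = rng.normal(5.0, 1.0)
                x = base + noise(len(cts))
            else:
                x = 2.0 + noise(len(cts))
                x += np.array([design.effect_log2fc if lin_of[ct] == mod else 0.0 for ct in cts])
        else:
            role = design.tf_roles[sym]
            if role.startswith("lineage_driver:"):
                lin = role.split(":")[1]
                x = 2.5 + noise(len(cts))
                x += np.array([design.effect_log2fc if lin_of[ct] == lin else 0.0 for ct in cts])
            elif role == "constitutive":
                x = 6.0 + noise(len(cts))
            elif role == "memory_driver":
                x = 2.5 + noise(len(cts))
                x += np.array(
                    [
                        design.memory_effect_log2fc if ct in design.memory_cell_types else 0.0
                        for ct in cts
                    ]
                )
            else:
                x = rng.normal(4.0, 0.7) + noise(len(cts))
        rows[sym] = np.exp2(x)
    data = pd.DataFrame.from_dict(rows, orient="index", columns=cts)
    data = data.loc[all_syms]
    data.index.name = "gene"
    return ExpressionMatrix(data)


# ---------------------------------------------------------------------------
# Emission + audit
# ---------------------------------------------------------------------------


def emit_dataset(design: SyntheticDesign, outdir) -> GroundTruth:
    """Write genome.fa, motifs.meme, tf_map.tsv, annotation.bed,
    expression.tsv, peaks/<cell_type>.narrowPeak and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)
    genome, library, annotation, truth = generate_genome_and_motifs(design)
    write_fasta(genome, outdir / "genome.fa")
    write_motifs_meme(library, outdir / "motifs.meme")
    write_tf_map(library, outdir / "tf_map.tsv")
    write_bed_annotation(annotation, outdir / "annotation.bed")
    write_expression(generate_expression(design), outdir / "expression.tsv")
    for ct in design.cell_types:
        write_narrowpeak(generate_peaks(design, ct), outdir / "peaks" / f"{ct}.narrowPeak")
    truth.to_json(outdir / "truth.json")
    with open(outdir / "design.json", "w") as fh:
        json.dump(asdict(design), fh, indent=1, sort_keys=True)
    return truth


def audit_truth(
    design: SyntheticDesign, outdir, p_threshold: float = 1e-5
) -> dict:
    """Re-scan the emitted genome to confirm every planted site is
    recoverable at the default motif threshold.  Returns a report with a
    ``passed`` flag and any missing sites."""
    from regnetrank.io import read_fasta, read_motifs_meme

    outdir = Path(outdir)
    if not (outdir / "genome.fa").exists():
        return {"passed": False, "error": "missing emitted files", "missing": []}
    genome = read_fasta(outdir / "genome.fa")
    library = read_motifs_meme(outdir / "motifs.meme", outdir / "tf_map.tsv")
    truth = GroundTruth.from_json(outdir / "truth.json")
    # scan only the planted windows, as single-window peaks
    peaks = PeakSet(
        [Peak(s["contig"], s["start"], s["end"], 5.0) for s in truth.planted_sites]
    )
    found = scan_peaks(genome, peaks, library, p_threshold=p_threshold)
    found_keys = {(s.contig, s.start, s.motif_id) for s in found}
    missing = [
        s
        for s in truth.planted_sites
        if (s["contig"], s["start"], s["motif_id"]) not in found_keys
    ]
    return {
        "passed": not missing,
        "n_planted": len(truth.planted_sites),
        "n_missing": len(missing),
        "missing": missing[:10],
    }


def motif_dissimilarity_ok(library: MotifLibrary, p_max: float = 1e-3) -> bool:
    """Check each motif's consensus is not a significant match to any other
    motif's score model (pairwise cross-match p > p_max)."""
    from regnetrank.motifs import encode_sequence, _score_windows

    models = {m.motif_id: build_score_model(m) for m in library}
    for m in library:
        cons = m.consensus()
        codes = encode_sequence(cons)[None, :]
        for other_id, model in models.items():
            if other_id == m.motif_id or model.length != m.length:
                continue
            p = model.pvalue(_score_windows(codes, model.logodds_int))[0]
            p_rc = model.pvalue(_score_windows(codes, model.rc_logodds_int()))[0]
            if min(p, p_rc) <= p_max:
                return False
    return True


# ---------------------------------------------------------------------------
# Matrix-level simulators (for statistical and clustering tests)
# ---------------------------------------------------------------------------


def make_null_matrix(
    n_tfs: int = 1000, n_cols: int = 20, mu: float = -3.0, sd: float = 0.3, seed: int = 0
) -> pd.DataFrame:
    """An i.i.d. log-normal score matrix with no planted effects: every
    score is 10^N(mu, sd)."""
    rng = np.random.default_rng(seed)
    vals = 10.0 ** rng.normal(mu, sd, size=(n_tfs, n_cols))
    return pd.DataFrame(
        vals,
        index=[f"TF{i+1:04d}" for i in range(n_tfs)],
        columns=[f"ct{j+1}" for j in range(n_cols)],
    )


def make_planted_matrix(
    n_tfs: int = 200,
    n_drivers: int = 5,
    target_cols: int = 3,
    background_cols: int = 17,
    effect_log10: float = 1.0,
    sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """A log-normal matrix where the first ``n_drivers`` TFs are shifted up
    by ``effect_log10`` (decades) in the target columns.  Returns the matrix
    and the driver names; target columns are named mem1..memK."""
    rng = np.random.default_rng(seed)
    cols = [f"mem{j+1}" for j in range(target_cols)] + [
        f"bg{j+1}" for j in range(background_cols)
    ]
    logs = rng.normal(-3.0, sd, size=(n_tfs, len(cols)))
    logs[:n_drivers, :target_cols] += effect_log10
    names = [f"TF{i+1:04d}" for i in range(n_tfs)]
    return pd.DataFrame(10.0**logs, index=names, columns=cols), names[:n_drivers]


def make_wave_matrix(
    n_clusters: int = 8,
    tfs_per_cluster: int = 12,
    n_cols: int = 20,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted wave patterns: each cluster has a smooth base profile and its
    members are positively scaled copies plus noise, so Pearson distance is
    the natural metric.  Returns (matrix, planted labels)."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 2 * np.pi, n_cols)
    rows, labels = [], []
    for c in range(n_clusters):
        phase = 2 * np.pi * c / n_clusters
        freq = 1 + (c % 3)
        base = np.sin(freq * t + phase)
        for _ in range(tfs_per_cluster):
            scale = rng.uniform(0.5, 2.0)
            shift = rng.normal(0.0, 0.2)
            rows.append(scale * base + shift + rng.normal(0.0, noise_sd, size=n_cols))
            labels.append(c)
    X = pd.DataFrame(
        rows,
        index=[f"TF{i+1:04d}" for i in range(len(rows))],
        columns=[f"ct{j+1}" for j in range(n_cols)],
    )
    return X, np.array(labels)
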