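"""Readers and writers for the standard formats the pipeline touches.

All genomic intervals are 0-based half-open internally; conversion to and
from 1-based conventions happens only at the file boundary.  Gene symbols are
the join key across expression, annotation and the motif map — case-sensitive
exact match, no aliasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """A genome as a mapping contig name -> upper-case DNA string over ACGTN."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(f"contig {name!r} contains illegal symbols {sorted(bad)}")

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if start < 0 or end > len(seq):
            raise ValueError(
                f"interval {contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start:end]

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


class Peak(NamedTuple):
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    neg_log10_p: float


@dataclass
class PeakSet:
    """Open-chromatin intervals carrying -log10(p) peak intensities.

    Records are kept sorted by (contig, start).
    """

    records: list[Peak]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.start >= r.end:
                raise ValueError(f"degenerate interval {r.contig}:{r.start}-{r.end}")
            if r.neg_log10_p < 0:
                raise ValueError(f"negative -log10(p) on {r.contig}:{r.start}-{r.end}")
        self.records = sorted(self.records, key=lambda r: (r.contig, r.start, r.end))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class ExpressionMatrix:
    """Gene x cell-type expression on a TPM-like nonnegative scale."""

    data: pd.DataFrame  # rows genes, columns cell types

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate cell-type label {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite expression value")
        if (vals < 0).any():
            raise ValueError("negative expression")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GeneAnnotation:
    """Per-gene TSS coordinates, strand, and a TF flag.

    ``table`` is indexed by gene symbol with columns contig, tss (0-based),
    strand ('+'/'-') and is_tf (bool, derived from the motif->TF mapping).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol {dup!r}")
        bad = set(self.table["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"illegal strand symbols {sorted(bad)}")
        if "is_tf" not in self.table.columns:
            self.table = self.table.assign(is_tf=False)

    def flag_tfs(self, tf_symbols: Sequence[str]) -> None:
        self.table["is_tf"] = self.table.index.isin(set(tf_symbols))

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def validate_against(self, genome: GenomeSequence) -> None:
        lengths = genome.lengths()
        for sym, row in self.table.iterrows():
            if row["contig"] not in lengths:
                raise ValueError(f"gene {sym}: unknown contig {row['contig']!r}")
            if not 0 <= row["tss"] < lengths[row["contig"]]:
                raise ValueError(f"gene {sym}: TSS {row['tss']} outside contig")


@dataclass
class MotifPWM:
    """A position probability matrix with the TF genes it is assigned to."""

    motif_id: str
    tfs: list[str]
    matrix: np.ndarray  # L x 4, rows sum to 1, columns A C G T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: PWM must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError(f"motif {self.motif_id}: length < 4")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-3:
            raise ValueError(f"motif {self.motif_id}: PWM row sums deviate from 1")
        # renormalise to machine precision
        self.matrix = self.matrix / sums[:, None]

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def information_bits(self) -> float:
        p = np.clip(self.matrix, 1e-12, 1.0)
        return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())


@dataclass
class MotifLibrary:
    motifs: list[MotifPWM]

    def __post_init__(self) -> None:
        ids = [m.motif_id for m in self.motifs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate motif ids")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def tf_symbols(self) -> list[str]:
        out: list[str] = []
        for m in self.motifs:
            out.extend(m.tfs)
        return sorted(set(out))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> GenomeSequence:
    """Read a FASTA genome; sequences are upper-cased and alphabet-checked."""
    contigs: dict[str, str] = {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no records")
    for rec in records:
        if rec.id in contigs:
            raise ParseError(f"{path}: duplicate contig header {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    # report illegal characters with their line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            bad = set(line.strip().upper()) - DNA_ALPHABET
            if bad:
                raise ParseError(
                    f"{path}:{lineno}: illegal sequence character(s) {sorted(bad)}"
                )
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# narrowPeak / BED
# ---------------------------------------------------------------------------


def read_narrowpeak(path, pvalue_column: int = 8) -> PeakSet:
    """Read narrowPeak (BED6+4) or BED with a designated -log10(p) column.

    ``pvalue_column`` is 1-based; the narrowPeak default is column 8.
    """
    records: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < max(3, pvalue_column):
                raise ParseError(f"{path}:{lineno}: expected >= {pvalue_column} columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                p = float(fields[pvalue_column - 1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            if p < 0:
                raise ParseError(f"{path}:{lineno}: negative -log10(p) column")
            records.append(Peak(fields[0], start, end, p))
    return PeakSet(records)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    """Emit BED6+4 narrowPeak with the -log10(p) intensity in column 8."""
    with open(path, "w") as fh:
        for i, r in enumerate(peaks):
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\tpeak_{i}\t0\t.\t0\t{r.neg_log10_p:.6g}\t-1\t-1\n"
            )


def read_bed_annotation(path, tf_symbols: Sequence[str] = ()) -> GeneAnnotation:
    """Read a BED6 gene annotation: name = gene symbol, TSS = start for '+'
    strand and end-1 for '-' strand."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires 6 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            strand = fields[5]
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            tss = start if strand == "+" else end - 1
            rows.append((fields[3], fields[0], tss, strand))
    if not rows:
        raise ParseError(f"{path}: no records")
    table = pd.DataFrame(rows, columns=["symbol", "contig", "tss", "strand"]).set_index(
        "symbol"
    )
    ann = GeneAnnotation(table)
    if tf_symbols:
        ann.flag_tfs(tf_symbols)
    return ann


def write_bed_annotation(annotation: GeneAnnotation, path, gene_span: int = 1) -> None:
    with open(path, "w") as fh:
        for sym, row in annotation.table.iterrows():
            if row["strand"] == "+":
                start, end = row["tss"], row["tss"] + gene_span
            else:
                start, end = row["tss"] - gene_span + 1, row["tss"] + 1
            fh.write(f"{row['contig']}\t{start}\t{end}\t{sym}\t0\t{row['strand']}\n")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x cell-type TSV (first column gene symbols, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no cell-type columns")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from None
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated gene symbol {dup!r}")
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative expression")
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", float_format="%.12g", index_label="gene")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------


def read_motifs_meme(path, tf_map_path) -> MotifLibrary:
    """Read a MEME-minimal motif file plus a two-column motif-id -> TF TSV.

    The sidecar mapping may be many-to-many.  Motifs lacking any TF mapping
    are dropped with a warning; map rows naming an absent motif warn too.
    """
    raw = _parse_meme_minimal(path)
    tf_map: dict[str, list[str]] = {}
    with open(tf_map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{tf_map_path}:{lineno}: expected 2 columns")
            tf_map.setdefault(fields[0], []).append(fields[1])
    motif_ids = {mid for mid, _, _ in raw}
    for mid in tf_map:
        if mid not in motif_ids:
            logger.warning("tf_map references absent motif %s", mid)
    motifs = []
    for mid, matrix, background in raw:
        tfs = tf_map.get(mid)
        if not tfs:
            logger.warning("motif %s has no TF mapping; dropped", mid)
            continue
        motifs.append(MotifPWM(mid, sorted(set(tfs)), matrix, background))
    return MotifLibrary(motifs)


def _parse_meme_minimal(path) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Parse MEME minimal format exactly (probabilities are not quantized)."""
    background = np.full(4, 0.25)
    out: list[tuple[str, np.ndarray, np.ndarray]] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freqs = {tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens), 2)}
            background = np.array([freqs[b] for b in "ACGT"])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < n and not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            if i >= n:
                raise ParseError(f"{path}: motif {motif_id} lacks a probability matrix")
            header = lines[i].strip()
            width = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(width):
                i += 1
                try:
                    row = [float(x) for x in lines[i].split()]
                except (IndexError, ValueError):
                    raise ParseError(
                        f"{path}:{i + 1}: bad probability row in motif {motif_id}"
                    ) from None
                if len(row) != 4:
                    raise ParseError(f"{path}:{i + 1}: expected 4 probabilities")
                if abs(sum(row) - 1.0) > 1e-3:
                    raise ParseError(
                        f"{path}:{i + 1}: motif {motif_id} row sums to {sum(row):.4f}, not 1"
                    )
                rows.append(row)
            out.append((motif_id, np.array(rows), background.copy()))
        i += 1
    if not out:
        raise ParseError(f"{path}: no motifs found")
    return out


def write_motifs_meme(library: MotifLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        if len(library.motifs) > 0:
            bg = library.motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(f"A {bg[0]:.6f} C {bg[1]:.6f} G {bg[2]:.6f} T {bg[3]:.6f}\n\n")
        for m in library:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} nsites= 20 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{x:.10f}" for x in row) + "\n")
            fh.write("\n")


def write_tf_map(library: MotifLibrary, path) -> None:
    with open(path, "w") as fh:
        for m in library:
            for tf in m.tfs:
                fh.write(f"{m.motif_id}\t{tf}\n")


# ---------------------------------------------------------------------------
# PageRank matrix TSV
# ---------------------------------------------------------------------------


def write_pagerank_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a TF x cell-type score matrix as TSV (12 significant digits)."""
    if matrix.size == 0:
        raise ValueError("refusing to write an empty matrix")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("refusing to write non-finite scores")
    matrix.to_csv(path, sep="\t", float_format="%.12g", index_label="tf")


def read_pagerank_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty matrix")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicated labels")
    return df.astype(float)
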