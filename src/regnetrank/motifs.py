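"""PWM scanning of open-chromatin peaks with exact match p-values.

Scores are integerized log-odds (log2 of PWM probability over background,
on a lattice of 1/1000 bit by default).  The null distribution of the score
of a random background sequence is computed exactly by dynamic programming:
the distributions of the per-position score contributions are convolved
across positions, giving the full probability mass function on the integer
lattice and hence an exact p-value for any observed score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from regnetrank.io import GenomeSequence, MotifLibrary, MotifPWM, PeakSet

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.int8)  # N and anything else -> 4
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

DEFAULT_GRANULARITY = 0.001  # bits per lattice step
DEFAULT_PSEUDOCOUNT = 1e-4
DEFAULT_P_THRESHOLD = 1e-5


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0 C=1 G=2 T=3, N (or other)=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ScoreModel:
    """Integerized log-odds matrix plus the exact null score distribution."""

    motif_id: str
    tfs: list[str]
    logodds_int: np.ndarray  # L x 4, int64, units of `granularity` bits
    granularity: float
    min_score: int  # smallest achievable total score
    survival: np.ndarray  # survival[s - min_score] = P(score >= s) under background
    background: np.ndarray

    @property
    def length(self) -> int:
        return self.logodds_int.shape[0]

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.survival) - 1

    def pvalue(self, score: int | np.ndarray) -> np.ndarray:
        """Exact P(background window scores >= score).

        p(min score) = 1; any score above the maximum has p = 0.
        """
        s = np.atleast_1d(np.asarray(score, dtype=np.int64))
        p = np.zeros(s.shape, dtype=float)
        below = s <= self.min_score
        inside = (s > self.min_score) & (s <= self.max_score)
        p[below] = 1.0
        p[inside] = self.survival[s[inside] - self.min_score]
        return p

    def rc_logodds_int(self) -> np.ndarray:
        """Log-odds of the reverse-complement motif (for minus-strand scans)."""
        return self.logodds_int[::-1, ::-1]


def build_score_model(
    pwm: MotifPWM,
    background: Sequence[float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    granularity: float = DEFAULT_GRANULARITY,
) -> ScoreModel:
    """Build the integerized log-odds model and its exact null distribution.

    ``background`` must be a length-4 probability vector with strictly
    positive entries (zero background frequencies are rejected rather than
    smoothed, so p-values are never silently altered).
    """
    if background is None:
        background = pwm.background
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background must be a length-4 probability vector")
    if (bg <= 0).any():
        raise ValueError("zero background frequency; supply a positive background")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    probs = pwm.matrix + pseudocount
    probs = probs / probs.sum(axis=1, keepdims=True)
    logodds = np.log2(probs / bg)
    lo_int = np.rint(logodds / granularity).astype(np.int64)

    # exact null distribution: convolve per-position score distributions
    mins = lo_int.min(axis=1)
    min_score = int(mins.sum())
    dist = np.ones(1, dtype=float)
    offset = 0  # dist[i] = P(partial score == offset + i)
    for pos in range(lo_int.shape[0]):
        row = lo_int[pos]
        lo, hi = int(row.min()), int(row.max())
        # the per-position distribution has only 4 support points, so the
        # convolution is 4 shifted adds rather than a dense convolve
        new = np.zeros(len(dist) + hi - lo, dtype=float)
        for letter in range(4):
            shift = int(row[letter]) - lo
            new[shift : shift + len(dist)] += bg[letter] * dist
        dist = new
        offset += lo
    assert offset == min_score
    # survival[s - min_score] = P(score >= s)
    survival = dist[::-1].cumsum()[::-1]
    survival = np.minimum(survival, 1.0)  # guard fp drift
    return ScoreModel(
        motif_id=pwm.motif_id,
        tfs=list(pwm.tfs),
        logodds_int=lo_int,
        granularity=granularity,
        min_score=min_score,
        survival=survival,
        background=bg,
    )


@dataclass(frozen=True)
class BindingSite:
    """A significant PWM match inside an open-chromatin peak."""

    motif_id: str
    tfs: tuple[str, ...]
    contig: str
    start: int
    end: int
    strand: str
    pvalue: float
    peak_neg_log10_p: float


def genome_background(genome: GenomeSequence) -> np.ndarray:
    """Genome-wide mononucleotide frequencies (N excluded)."""
    counts = np.zeros(4, dtype=float)
    for seq in genome.contigs.values():
        codes = encode_sequence(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("genome contains no unambiguous bases")
    return counts / counts.sum()


def build_models(
    library: MotifLibrary,
    background: Sequence[float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    granularity: float = DEFAULT_GRANULARITY,
) -> list[ScoreModel]:
    return [build_score_model(m, background, pseudocount, granularity) for m in library]


def _score_windows(windows: np.ndarray, lo_int: np.ndarray) -> np.ndarray:
    """Total integer scores of all windows (n_windows x L codes)."""
    L = lo_int.shape[0]
    flat = lo_int.reshape(-1)
    idx = windows.astype(np.int64) + (np.arange(L, dtype=np.int64) * 4)[None, :]
    return flat[idx].sum(axis=1)


def _logodds_stack(models: Sequence[ScoreModel]) -> np.ndarray:
    """Interleaved (2M x 4L) matrix of forward / reverse-complement
    log-odds, flattened position-major to match one-hot window encoding."""
    rows = []
    for m in models:
        rows.append(m.logodds_int.reshape(-1))
        rows.append(m.rc_logodds_int().reshape(-1))
    return np.array(rows, dtype=np.float64)


def scan_peaks(
    genome: GenomeSequence,
    peaks: PeakSet,
    library: MotifLibrary | Iterable[ScoreModel],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    background: Sequence[float] | None = None,
) -> list[BindingSite]:
    """Scan every window of each peak, on both strands, for PWM matches.

    A site is emitted where the exact match p-value is <= ``p_threshold``.
    When the same motif matches at the same start on both strands, only the
    better p-value is kept (ties resolve to '+').  Windows containing N are
    skipped and counted in the log.  If ``background`` is None the
    genome-wide mononucleotide composition is used.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    if isinstance(library, MotifLibrary):
        if background is None:
            background = genome_background(genome)
        models = build_models(library, background)
    else:
        models = list(library)

    lengths = genome.lengths()
    encoded: dict[str, np.ndarray] = {}
    by_length: dict[int, list[ScoreModel]] = {}
    for m in models:
        by_length.setdefault(m.length, []).append(m)
    stacks = {L: _logodds_stack(group) for L, group in by_length.items()}

    sites: list[BindingSite] = []
    n_skipped = 0
    for peak in peaks:
        if peak.contig not in lengths:
            raise ValueError(f"peak on unknown contig {peak.contig!r}")
        if peak.start < 0 or peak.end > lengths[peak.contig]:
            raise ValueError(
                f"peak {peak.contig}:{peak.start}-{peak.end} extends past contig end"
            )
        if peak.contig not in encoded:
            encoded[peak.contig] = encode_sequence(genome.contigs[peak.contig])
        codes = encoded[peak.contig][peak.start : peak.end]
        for L, group in by_length.items():
            if peak.end - peak.start < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(codes, L)
            valid = (windows < 4).all(axis=1)
            n_skipped += int((~valid).sum())
            if not valid.any():
                continue
            vwin = windows[valid]
            starts = peak.start + np.nonzero(valid)[0]
            # one-hot the windows once, then score every model of this
            # length (forward and reverse strand) in a single matmul
            lo_stack = stacks[L]
            n = vwin.shape[0]
            onehot = np.zeros((n, 4 * L), dtype=np.float64)
            onehot[np.arange(n)[:, None], vwin.astype(np.int64) + 4 * np.arange(L)] = 1.0
            scores = np.rint(lo_stack @ onehot.T).astype(np.int64)  # (2M, n)
            for mi, model in enumerate(group):
                p_fwd = model.pvalue(scores[2 * mi])
                p_rev = model.pvalue(scores[2 * mi + 1])
                take_rev = p_rev < p_fwd  # ties -> '+'
                best_p = np.where(take_rev, p_rev, p_fwd)
                hit = best_p <= p_threshold
                for j in np.nonzero(hit)[0]:
                    sites.append(
                        BindingSite(
                            motif_id=model.motif_id,
                            tfs=tuple(model.tfs),
                            contig=peak.contig,
                            start=int(starts[j]),
                            end=int(starts[j]) + L,
                            strand="-" if take_rev[j] else "+",
                            pvalue=float(best_p[j]),
                            peak_neg_log10_p=peak.neg_log10_p,
                        )
                    )
    if n_skipped:
        logger.info("skipped %d windows containing N", n_skipped)
    sites.sort(key=lambda s: (s.contig, s.start, s.motif_id, s.strand))
    return sites


def write_sites_bed(sites: Sequence[BindingSite], path) -> None:
    """Export sites as BED6+2: name = motif id, extra columns p-value and
    the containing peak's -log10(p)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.start}\t{s.end}\t{s.motif_id}\t0\t{s.strand}"
                f"\t{s.pvalue:.6g}\t{s.peak_neg_log10_p:.6g}\n"
            )


def read_sites_bed(path, library: MotifLibrary) -> list[BindingSite]:
    tf_of = {m.motif_id: tuple(m.tfs) for m in library}
    sites = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            sites.append(
                BindingSite(
                    motif_id=f[3],
                    tfs=tf_of.get(f[3], ()),
                    contig=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5],
                    pvalue=float(f[6]),
                    peak_neg_log10_p=float(f[7]),
                )
            )
    return sites
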