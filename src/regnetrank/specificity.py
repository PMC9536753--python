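"""Downstream statistics on the TF x cell-type PageRank matrix.

Cell-type-specific TFs are called by contrasting a target group of samples
against a background group.  PageRank scores are treated as log-normal
(checked per TF with Shapiro-Wilk), so t-tests run on log10 scores: Welch's
unequal-variance t-test when the target group has >= 3 samples, otherwise a
one-sample t-test of the background against the target mean.  Fold changes
are computed on raw-score group means.  Preset cutoff tiers:

    lineage          p < 0.001, log2 FC > 1
    sublineage       p < 0.005, log2 FC > 0.5   (e.g. myeloid vs lymphoid)
    memory           p < 0.1,   no FC cutoff
    tissue_resident  p < 0.1,   log2 FC > 0.5

Constitutively active TFs are those in the top decile of mean PageRank with
a coefficient of variation below 0.5.  A balanced-resampling permutation
scheme guards the memory contrast against group-size imbalance, and Fisher's
exact test measures cross-species overlap of TF lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CUTOFF_TIERS: dict[str, tuple[float, float | None]] = {
    "lineage": (0.001, 1.0),
    "sublineage": (0.005, 0.5),
    "memory": (0.1, None),
    "tissue_resident": (0.1, 0.5),
}


@dataclass
class GroupDesign:
    """A target-vs-background split of the matrix columns."""

    target: set[str]
    background: set[str]
    excluded: set[str] = field(default_factory=set)
    label: str = ""

    def __post_init__(self) -> None:
        self.target, self.background = set(self.target), set(self.background)
        self.excluded = set(self.excluded)
        if self.target & self.background:
            raise ValueError("target and background overlap")
        if not self.target or not self.background:
            raise ValueError("target and background must both be non-empty")

    def validate_columns(self, columns: Iterable[str]) -> None:
        cols = set(columns)
        missing = (self.target | self.background) - cols
        if missing:
            raise ValueError(f"design names absent columns: {sorted(missing)}")


def znormalize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-normalization (sample sd); constant rows become zeros."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def find_active_tfs(
    matrix: pd.DataFrame, top_fraction: float = 0.10, cv_max: float = 0.5
) -> list[str]:
    """Constitutively active TFs: top decile of mean raw PageRank, CV < cv_max.

    TFs with zero mean (CV undefined) are excluded and logged.
    """
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    zero = means == 0
    if zero.any():
        logger.info("%d TFs with zero mean excluded from CV", int(zero.sum()))
    n_top = int(np.ceil(top_fraction * len(matrix)))
    top = set(means.sort_values(ascending=False, kind="stable").index[:n_top])
    cv = sds[~zero] / means[~zero]
    return sorted(tf for tf in cv.index if tf in top and cv[tf] < cv_max)


def lognormality_fraction(
    matrix: pd.DataFrame, design: GroupDesign, alpha: float = 0.05
) -> float:
    """Fraction of TFs whose log10 scores pass Shapiro-Wilk in both groups.

    A TF fails if the test rejects normality (p < alpha) in either group;
    groups of identical values (test undefined) count as failures.
    """
    design.validate_columns(matrix.columns)
    groups = [sorted(design.target), sorted(design.background)]
    for g in groups:
        if len(g) < 3:
            raise ValueError("Shapiro-Wilk needs group sizes >= 3")
    logs = np.log10(matrix.to_numpy(dtype=float))
    if not np.isfinite(logs).all():
        raise ValueError("nonpositive scores; log undefined")
    cols = {c: i for i, c in enumerate(matrix.columns)}
    n_pass = 0
    for row in logs:
        ok = True
        for g in groups:
            vals = row[[cols[c] for c in g]]
            if np.ptp(vals) == 0:
                logger.debug("identical values in group; counted as fail")
                ok = False
                break
            if stats.shapiro(vals).pvalue < alpha:
                ok = False
                break
        n_pass += ok
    return n_pass / len(matrix)


def specific_tfs(
    matrix: pd.DataFrame,
    design: GroupDesign,
    p_cut: float,
    lfc_cut: float | None = None,
    equal_var: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Call TFs specifically active in the target group.

    Returns one row per TF with columns pvalue, log2_fc, test and passed;
    passed requires p < p_cut and (when a cutoff is given) log2 FC > lfc_cut,
    both strict.  Raw p-values by default; ``bh`` switches to
    Benjamini-Hochberg-adjusted ones.
    """
    design.validate_columns(matrix.columns)
    target = sorted(design.target)
    background = sorted(design.background - design.excluded)
    if not background:
        raise ValueError("empty background after exclusions")
    t_raw = matrix[target].to_numpy(dtype=float)
    b_raw = matrix[background].to_numpy(dtype=float)
    if (t_raw <= 0).any() or (b_raw <= 0).any():
        raise ValueError("nonpositive PageRank score; log undefined")
    t_log, b_log = np.log10(t_raw), np.log10(b_raw)

    if len(target) >= 3:
        test_name = "welch" if not equal_var else "student"
        res = stats.ttest_ind(t_log, b_log, axis=1, equal_var=equal_var)
        pvals = np.asarray(res.pvalue)
    else:
        # tiny target group: one-sample t-test of the background against
        # the target mean
        test_name = "one_sample"
        res = stats.ttest_1samp(b_log, popmean=t_log.mean(axis=1, keepdims=True), axis=1)
        pvals = np.asarray(res.pvalue)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    if bh:
        pvals = stats.false_discovery_control(pvals, method="bh")
    lfc = np.log2(t_raw.mean(axis=1) / b_raw.mean(axis=1))
    passed = pvals < p_cut
    if lfc_cut is not None:
        passed = passed & (lfc > lfc_cut)
    out = pd.DataFrame(
        {
            "pvalue": pvals,
            "log2_fc": lfc,
            "test": test_name,
            "passed": passed,
        },
        index=matrix.index.rename("tf"),
    )
    return out


def filter_gene_list(calls: pd.DataFrame, exclusion_list: Sequence[str]) -> pd.DataFrame:
    """Drop calls for excluded gene symbols (e.g. digestion-related genes)."""
    excl = set(exclusion_list)
    unknown = excl - set(calls.index)
    if unknown:
        logger.warning("%d exclusion symbols not in call list", len(unknown))
    keep = calls[~calls.index.isin(excl)]
    n_dropped = len(calls) - len(keep)
    if n_dropped:
        logger.info("filtered %d calls via exclusion list", n_dropped)
    return keep


def balanced_resampling(
    matrix: pd.DataFrame,
    target: Sequence[str],
    background_pool: Sequence[str],
    n_reps: int = 1000,
    p_cut: float = 0.1,
    seed: int = 0,
) -> pd.Series:
    """Balanced permutation scheme for a small target group.

    Each repetition draws len(target) background columns without replacement
    and runs the Welch test of target vs the drawn columns at ``p_cut``;
    the returned Series maps TF -> selection frequency in [0, 1], sorted
    descending (ties broken by TF name for determinism).
    """
    target = sorted(target)
    pool = sorted(set(background_pool) - set(target))
    if len(pool) < len(target):
        raise ValueError("background pool smaller than target group")
    rng = np.random.default_rng(seed)
    t_log = np.log10(matrix[target].to_numpy(dtype=float))
    pool_log = np.log10(matrix[pool].to_numpy(dtype=float))
    counts = np.zeros(len(matrix), dtype=int)
    for _ in range(n_reps):
        idx = rng.choice(len(pool), size=len(target), replace=False)
        b_log = pool_log[:, idx]
        with np.errstate(invalid="ignore"):
            pv = np.asarray(stats.ttest_ind(t_log, b_log, axis=1, equal_var=False).pvalue)
        pv = np.where(np.isnan(pv), 1.0, pv)
        counts += pv < p_cut
    freq = pd.Series(counts / n_reps, index=matrix.index.rename("tf"))
    order = np.lexsort((freq.index.to_numpy(), -freq.to_numpy()))
    return freq.iloc[order]


def fisher_overlap(
    list_a: Sequence[str], list_b: Sequence[str], universe_size: int
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the overlap of two TF lists.

    Returns (odds ratio, p-value) of the 2x2 table
    (|A and B|, |A only|, |B only|, rest of universe).
    """
    a, b = set(list_a), set(list_b)
    n_ab = len(a & b)
    n_a, n_b = len(a - b), len(b - a)
    if universe_size < len(a | b):
        raise ValueError("universe smaller than the union of the lists")
    rest = universe_size - n_ab - n_a - n_b
    odds, p = stats.fisher_exact([[n_ab, n_a], [n_b, rest]], alternative="two-sided")
    return float(odds), float(p)
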