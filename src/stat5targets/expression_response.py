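"""Differential expression of nascent (4sU) RNA, replicate QC and CAGE
time-course dynamics.

The DEG caller normalises libraries by median-of-ratios size factors,
forms pseudocounted fold changes between condition means, and tests each
gene with an exact conditional binomial test on the pooled normalised
counts (null proportion = the stimulated libraries' share), followed by
Benjamini-Hochberg FDR control.  CAGE tag series are normalised as
relative log expression (RLE, median-of-ratios across libraries) and
classified as immediate, delayed or unresponsive from the timing and
magnitude of their maximal fold change over t = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomics_io import CountTable, ValidationError

logger = logging.getLogger(__name__)

CONDITION_STIMULATED = "EPO+"
CONDITION_CONTROL = "EPO-"

DEG_CALLS = ("induced", "repressed", "unchanged")
DYNAMICS_CLASSES = ("immediate", "delayed", "unresponsive")


@dataclass(frozen=True)
class DynamicsCall:
    call: str
    peak_time: float  # minutes
    max_fold_over_t0: float

    def __post_init__(self) -> None:
        if self.call not in DYNAMICS_CLASSES:
            raise ValueError(f"unknown dynamics class {self.call!r}")


# ---------------------------------------------------------------------------
# FPKM and size factors
# ---------------------------------------------------------------------------


def fpkm(table: CountTable) -> pd.DataFrame:
    """FPKM = count * 1e9 / (gene_length * library_size), per gene x sample."""
    lib = table.library_sizes()
    if (lib <= 0).any():
        zero = list(lib.index[lib <= 0])
        raise ValidationError(f"zero library size for samples {zero}")
    return (
        table.counts.astype(float)
        .mul(1e9)
        .div(table.gene_lengths, axis=0)
        .div(lib, axis=1)
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    Computed over genes with all-positive counts; falls back to
    library-size ratios (with a warning) when no such gene exists.
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if positive.sum() == 0:
        logger.warning(
            "no gene has positive counts in every library; "
            "falling back to total-count size factors"
        )
        lib = values.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    else:
        pos = values[positive]
        geomean = np.exp(np.log(pos).mean(axis=1, keepdims=True))
        sf = np.median(pos / geomean, axis=0)
    return pd.Series(sf, index=counts.columns)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def _doubled_tail_binomial(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Exact two-sided binomial p-values (doubled smaller tail, capped at 1)."""
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    p = 2.0 * np.minimum(lower, upper)
    return np.clip(p, 0.0, 1.0)


def call_degs(
    table: CountTable,
    min_fold: float = 1.5,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
    min_mean_count: float = 10.0,
    stimulated: str = CONDITION_STIMULATED,
    control: str = CONDITION_CONTROL,
) -> pd.DataFrame:
    """Call induced / repressed / unchanged genes between two conditions.

    Returns a DataFrame indexed by gene with columns fold_change,
    mean_fpkm, p_value, fdr, call.  Genes below ``min_mean_count``
    normalised mean counts are reported but not tested (p = fdr = 1).
    """
    cond = table.conditions
    plus = [s for s in table.samples if cond[s] == stimulated]
    minus = [s for s in table.samples if cond[s] == control]
    if not plus or not minus:
        raise ValidationError(
            f"need at least one replicate per condition ({stimulated}/{control})"
        )
    sf = size_factors(table.counts)
    norm = table.counts.div(sf, axis=1)
    mean_plus = norm[plus].mean(axis=1)
    mean_minus = norm[minus].mean(axis=1)
    fold = (mean_plus + pseudocount) / (mean_minus + pseudocount)

    fpkm_values = fpkm(table)
    mean_fpkm = (fpkm_values[plus].mean(axis=1) + fpkm_values[minus].mean(axis=1)) / 2

    pooled_plus = np.rint(norm[plus].sum(axis=1).to_numpy())
    pooled_minus = np.rint(norm[minus].sum(axis=1).to_numpy())
    n_pooled = (pooled_plus + pooled_minus).astype(np.int64)
    # after size-factor normalisation every library sits on a common scale,
    # so the stimulated share of the pool is the replicate-count share
    p_share = len(plus) / (len(plus) + len(minus))
    p_raw = np.ones(len(table.genes))
    nonzero = n_pooled > 0
    p_raw[nonzero] = _doubled_tail_binomial(
        pooled_plus[nonzero].astype(np.int64), n_pooled[nonzero], p_share
    )

    testable = (norm.mean(axis=1) >= min_mean_count).to_numpy() & nonzero
    fdr = np.ones(len(p_raw))
    if testable.any():
        fdr[testable] = multipletests(p_raw[testable], method="fdr_bh")[1]

    calls = np.full(len(p_raw), "unchanged", dtype=object)
    significant = testable & (fdr < fdr_threshold)
    calls[significant & (fold.to_numpy() >= min_fold)] = "induced"
    calls[significant & (fold.to_numpy() <= 1.0 / min_fold)] = "repressed"

    out = pd.DataFrame(
        {
            "fold_change": fold,
            "mean_fpkm": mean_fpkm,
            "p_value": np.where(testable, p_raw, 1.0),
            "fdr": fdr,
            "call": calls,
        },
        index=table.counts.index,
    )
    out.index.name = "gene_id"
    return out


def replicate_correlation(
    table: CountTable, min_fpkm: float = 0.0
) -> dict[str, float]:
    """Per-condition Spearman correlation of log-scale FPKM between replicates.

    Genes expressed (FPKM > ``min_fpkm``) in either replicate of a pair
    contribute; with more than two replicates all pairwise coefficients
    are averaged.
    """
    fpkm_values = fpkm(table)
    out: dict[str, float] = {}
    for condition in table.conditions.unique():
        samples = [s for s in table.samples if table.conditions[s] == condition]
        if len(samples) < 2:
            raise ValidationError(
                f"condition {condition!r} has fewer than two replicates"
            )
        rs = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a = fpkm_values[samples[i]]
                b = fpkm_values[samples[j]]
                expressed = (a > min_fpkm) | (b > min_fpkm)
                loga = np.log2(a[expressed] + 1e-9)
                logb = np.log2(b[expressed] + 1e-9)
                rs.append(stats.spearmanr(loga, logb).statistic)
        out[condition] = float(np.mean(rs))
    return out


# ---------------------------------------------------------------------------
# CAGE time series
# ---------------------------------------------------------------------------


@dataclass
class CageExperiment:
    """CAGE tag counts for promoter/enhancer regions across a time course.

    ``counts`` is regions x libraries; ``times`` maps each library to its
    minute post-stimulation and ``replicates`` to a replicate index.
    """

    counts: pd.DataFrame
    times: pd.Series
    replicates: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("CAGE counts must be non-negative")
        times = sorted(self.times.unique())
        if len(times) < 2:
            raise ValidationError("need at least two time points")
        if times[0] != 0:
            raise ValidationError("time course must include t = 0")

    @property
    def time_grid(self) -> list[float]:
        return sorted(self.times.unique())


def rle_normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Relative log expression normalisation across libraries.

    Per-library scale factor = median over all-positive regions of
    (count / per-region geometric mean across libraries); when every
    region contains a zero, falls back to upper-quartile scaling with a
    warning.  Returns (scale factors, rle = log2(count/scale + 1)).
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if positive.sum() == 0:
        logger.warning(
            "every CAGE region contains a zero count; "
            "falling back to upper-quartile scaling"
        )
        uq = np.percentile(values, 75, axis=0)
        if (uq <= 0).any():
            raise ValidationError("upper-quartile scaling impossible: zero quartiles")
        scale = uq / np.exp(np.mean(np.log(uq)))
    else:
        pos = values[positive]
        geomean = np.exp(np.log(pos).mean(axis=1, keepdims=True))
        scale = np.median(pos / geomean, axis=0)
    scale_s = pd.Series(scale, index=counts.columns)
    rle = np.log2(counts.div(scale_s, axis=1) + 1.0)
    return scale_s, rle


def classify_dynamics(
    times: np.ndarray,
    values: np.ndarray,
    response_fold: float = 2.0,
    immediate_cutoff: float = 60.0,
    pseudocount: float = 1.0,
) -> DynamicsCall:
    """Classify a normalised time course as immediate/delayed/unresponsive.

    ``values`` are scale-normalised linear tag counts on the (strictly
    increasing) ``times`` grid starting at 0.  The series is unresponsive
    when its maximal pseudocounted fold over t=0 stays below
    ``response_fold``; otherwise immediate if the maximum occurs at or
    before ``immediate_cutoff`` minutes, else delayed.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 2:
        raise ValidationError("a single time point cannot be classified")
    if len(times) != len(values):
        raise ValidationError("times and values must align")
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing from 0")
    folds = (values + pseudocount) / (values[0] + pseudocount)
    later = folds[1:]
    best = int(np.argmax(later)) + 1
    max_fold = float(folds[best])
    peak_time = float(times[best])
    if max_fold < response_fold:
        return DynamicsCall("unresponsive", peak_time, max_fold)
    if peak_time <= immediate_cutoff:
        return DynamicsCall("immediate", peak_time, max_fold)
    return DynamicsCall("delayed", peak_time, max_fold)


def classify_cage_dynamics(
    experiment: CageExperiment,
    response_fold: float = 2.0,
    immediate_cutoff: float = 60.0,
) -> pd.DataFrame:
    """RLE-normalise a CAGE experiment and classify every region.

    Replicates are averaged on the normalised linear scale per time point
    before classification.  Returns a DataFrame with call, peak_time and
    max_fold_over_t0 per region.
    """
    scale, _ = rle_normalize(experiment.counts)
    norm = experiment.counts.div(scale, axis=1)
    grid = experiment.time_grid
    per_time = np.column_stack(
        [
            norm.loc[:, experiment.times[experiment.times == t].index].mean(axis=1)
            for t in grid
        ]
    )
    rows = []
    for i, region in enumerate(norm.index):
        call = classify_dynamics(
            np.asarray(grid), per_time[i], response_fold, immediate_cutoff
        )
        rows.append((region, call.call, call.peak_time, call.max_fold_over_t0))
    return pd.DataFrame(
        rows, columns=["region_id", "call", "peak_time", "max_fold_over_t0"]
    ).set_index("region_id")
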