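"""Profiling non-conversion errors on known-unmethylated control DNA.

Unmethylated controls (chloroplast, phage lambda, Drosophila) have no true
cytosine methylation, so every unconverted cytosine is an error. This module
summarises those errors three ways: per-read (category mixture and positional
profiles by bisulphite strand), per-window (rates, a binomial-null
variance-inflation statistic, GC/coverage correlations), and as a fitted beta
distribution of window-level error rates — the error model used downstream
for estimation and state classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from bsconv.io_formats import (
    CytosineSiteRecord,
    GenomeSequence,
    ReadCalls,
    STRAND_CLASSES,
    gc_fraction,
)


@dataclass(frozen=True)
class BetaErrorModel:
    """Beta distribution of non-conversion error rates across the genome.

    Shape parameters ``a`` and ``b``; the implied mean error rate is
    ``a / (a + b)``.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"beta shape parameters must be positive, got {self}")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def variance(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.a, self.b, size=size)


@dataclass(frozen=True)
class WindowStats:
    """Pooled unconverted/total counts for one genomic window.

    Coordinates are 0-based half-open. ``rate`` is NaN when the window has
    no covered cytosines; such windows are kept, not dropped.
    """

    chrom: str
    start: int
    end: int
    y: int
    n: int
    mean_coverage: float
    gc: float
    n_cg: int
    n_chg: int
    n_chh: int

    @property
    def rate(self) -> float:
        return self.y / self.n if self.n > 0 else math.nan

    @property
    def n_sites(self) -> int:
        return self.n_cg + self.n_chg + self.n_chh


@dataclass(frozen=True)
class ReadCategoryCounts:
    """Counts of reads that are fully converted, partially or fully unconverted."""

    fully_converted: int
    partial: int
    fully_unconverted: int

    @property
    def total(self) -> int:
        return self.fully_converted + self.partial + self.fully_unconverted


@dataclass
class PositionalProfile:
    """Per-offset (unconverted, total) cytosine counts for one strand class."""

    strand_class: str
    unconverted: np.ndarray
    total: np.ndarray

    def rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.unconverted / self.total, np.nan)


def window_rates(
    records: Iterable[CytosineSiteRecord],
    window_size: int,
    region: tuple[str, int, int],
    genome: Optional[GenomeSequence] = None,
) -> list[WindowStats]:
    """Tile ``region`` with consecutive windows and pool site counts per window.

    ``region`` is ``(chrom, start, end)`` in 0-based half-open coordinates;
    the last window may be shorter. Records must be position-sorted and lie
    inside the region. GC content is computed from ``genome`` when given.
    """
    chrom, start, end = region
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not (0 <= start < end):
        raise ValueError(f"invalid region ({chrom}, {start}, {end})")
    n_windows = math.ceil((end - start) / window_size)
    y = np.zeros(n_windows, dtype=np.int64)
    n = np.zeros(n_windows, dtype=np.int64)
    ctx_counts = {"CG": np.zeros(n_windows, dtype=np.int64),
                  "CHG": np.zeros(n_windows, dtype=np.int64),
                  "CHH": np.zeros(n_windows, dtype=np.int64)}
    sites = np.zeros(n_windows, dtype=np.int64)

    last_pos = -1
    for rec in records:
        if rec.chrom != chrom or not (start < rec.pos <= end):
            raise ValueError(
                f"record at {rec.chrom}:{rec.pos} outside region "
                f"{chrom}:{start + 1}-{end}"
            )
        if rec.pos < last_pos:
            raise ValueError(f"records not sorted by position near {rec.pos}")
        last_pos = rec.pos
        widx = (rec.pos - 1 - start) // window_size
        y[widx] += rec.meth_count
        n[widx] += rec.coverage
        ctx_counts[rec.context][widx] += 1
        sites[widx] += 1

    windows = []
    for i in range(n_windows):
        w_start = start + i * window_size
        w_end = min(w_start + window_size, end)
        if genome is not None:
            gc = gc_fraction(genome.sequence, w_start, min(w_end, len(genome.sequence)))
        else:
            gc = math.nan
        windows.append(
            WindowStats(
                chrom=chrom,
                start=w_start,
                end=w_end,
                y=int(y[i]),
                n=int(n[i]),
                mean_coverage=float(n[i] / sites[i]) if sites[i] else math.nan,
                gc=gc,
                n_cg=int(ctx_counts["CG"][i]),
                n_chg=int(ctx_counts["CHG"][i]),
                n_chh=int(ctx_counts["CHH"][i]),
            )
        )
    return windows


def overall_rate(records: Iterable[CytosineSiteRecord]) -> tuple[int, int, float]:
    """Pooled (y, n, y/n) non-conversion rate over all sites."""
    y = n = 0
    for rec in records:
        y += rec.meth_count
        n += rec.coverage
    if n == 0:
        raise ValueError("zero total coverage; cannot compute a rate")
    return y, n, y / n


def fit_beta_mom(mean: float, variance: float) -> BetaErrorModel:
    """Fit beta shape parameters from a mean and variance by method of moments.

    Inverts the beta moments: a = mu*(mu*(1-mu)/var - 1) and
    b = (1-mu)*(mu*(1-mu)/var - 1). The variance must be strictly less than
    mu*(1-mu), the Bernoulli bound, or the inversion has no positive solution.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    bound = mean * (1.0 - mean)
    if not (0.0 < variance < bound):
        raise ValueError(
            f"variance must be in (0, {bound:.6g}) for mean {mean}; got {variance}"
        )
    scale = bound / variance - 1.0
    return BetaErrorModel(a=mean * scale, b=(1.0 - mean) * scale)


def fit_error_model_from_windows(
    windows: Sequence[WindowStats],
    correct_binomial_noise: bool = False,
) -> BetaErrorModel:
    """Fit the beta error model to the sample moments of window rates.

    Uses the unbiased (m-1 denominator) sample variance of per-window rates;
    windows without coverage are excluded.

    The observed variance of window rates is the variance of the true
    per-window error rates plus the binomial sampling variance of each
    window's rate estimate, roughly mean(r(1-r)/n). At low per-window read
    counts this inflates the variance and shrinks the fitted shape
    parameters. ``correct_binomial_noise`` subtracts the estimated sampling
    component before inverting the moments; the default leaves the plain
    moment fit, appropriate when windows hold hundreds of reads or more.
    """
    kept = [w for w in windows if w.n > 0]
    rates = np.array([w.rate for w in kept], dtype=float)
    if rates.size < 2:
        raise ValueError("need >= 2 windows with defined rates")
    mu = float(rates.mean())
    var = float(rates.var(ddof=1))
    if var == 0.0:
        raise ValueError("window rates are all identical; beta fit undefined")
    if correct_binomial_noise:
        sampling = float(np.mean([w.rate * (1 - w.rate) / w.n for w in kept]))
        if var - sampling <= 0.0:
            raise ValueError(
                "window variance is within binomial sampling noise; "
                "no excess variation to fit a beta distribution to"
            )
        var -= sampling
    return fit_beta_mom(mu, var)


def variance_inflation(
    windows: Sequence[WindowStats],
    global_rate: float,
    n_sims: int = 200,
    seed: int | None = None,
) -> float:
    """Observed between-window rate variance over its binomial-null expectation.

    The null holds each window's coverage fixed and draws its unconverted
    count binomially at the single global rate, as many times as ``n_sims``;
    the statistic is the observed sample variance of window rates divided by
    the mean sample variance across simulated window sets. A ratio near 1
    means the window-to-window variation is pure binomial sampling noise;
    ratios well above 1 indicate genuine spatial variation in error rates.
    """
    ns = np.array([w.n for w in windows if w.n > 0], dtype=np.int64)
    obs = np.array([w.rate for w in windows if w.n > 0], dtype=float)
    if ns.size < 2:
        raise ValueError("need >= 2 windows with coverage")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    observed_var = obs.var(ddof=1)
    sim_y = rng.binomial(ns[None, :], global_rate, size=(n_sims, ns.size))
    sim_var = (sim_y / ns[None, :]).var(ddof=1, axis=1)
    return float(observed_var / sim_var.mean())


def variance_inflation_analytic(
    windows: Sequence[WindowStats], global_rate: float
) -> float:
    """Analytic-null variant of :func:`variance_inflation`.

    For independent window rates sharing mean g, the expected sample variance
    equals the mean of the per-window binomial variances g(1-g)/n_i; used as
    a fast cross-check of the simulated null.
    """
    ns = np.array([w.n for w in windows if w.n > 0], dtype=np.int64)
    obs = np.array([w.rate for w in windows if w.n > 0], dtype=float)
    if ns.size < 2:
        raise ValueError("need >= 2 windows with coverage")
    expected = float(np.mean(global_rate * (1.0 - global_rate) / ns))
    return float(obs.var(ddof=1) / expected)


def read_categories(
    reads: Iterable[ReadCalls],
) -> tuple[ReadCategoryCounts, list[float]]:
    """Sort reads into fully converted / partial / fully unconverted.

    Returns the category counts plus each read's unconverted fraction
    (the histogram substrate). Reads without cytosines are skipped.
    """
    fully_converted = partial = fully_unconverted = 0
    fractions: list[float] = []
    for read in reads:
        if read.n_calls == 0:
            continue
        frac = read.unconverted_fraction
        fractions.append(frac)
        if frac == 0.0:
            fully_converted += 1
        elif frac == 1.0:
            fully_unconverted += 1
        else:
            partial += 1
    return (
        ReadCategoryCounts(fully_converted, partial, fully_unconverted),
        fractions,
    )


def positional_profile(
    reads: Iterable[ReadCalls], max_offset: int
) -> dict[str, PositionalProfile]:
    """Pool unconverted/total cytosine counts per read offset and strand class.

    Rising rates towards high offsets (the 3' end) are the signature of
    nick-initiated strand displacement, which overwrites downstream
    cytosines with methylated bases.
    """
    if max_offset < 1:
        raise ValueError("max_offset must be >= 1")
    profiles = {
        sc: PositionalProfile(
            strand_class=sc,
            unconverted=np.zeros(max_offset, dtype=np.int64),
            total=np.zeros(max_offset, dtype=np.int64),
        )
        for sc in STRAND_CLASSES
    }
    for read in reads:
        prof = profiles[read.strand_class]
        for call in read.calls:
            if call.read_offset < max_offset:
                prof.total[call.read_offset] += 1
                if call.unconverted:
                    prof.unconverted[call.read_offset] += 1
    return profiles


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Pairs where either entry is NaN are dropped; at least 3 complete pairs
    are required.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(xa) | np.isnan(ya))
    if mask.sum() < 3:
        raise ValueError("need >= 3 complete pairs")
    rho, _ = stats.spearmanr(xa[mask], ya[mask])
    return float(rho)
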