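"""Error-corrected binomial estimation of methylation level.

Of n reads covering the cytosines of a locus, y are observed unconverted.
With non-conversion rate eps1 (a truly unmethylated cytosine read back as
methylated) and false-conversion rate eps2 (a truly methylated cytosine read
as converted), a read is observed unconverted with probability

    p = theta * (1 - eps2) + (1 - theta) * eps1

where theta is the true methylation level. The likelihood is Binomial(y; n, p)
and the maximum-likelihood estimate has the closed form

    theta_hat = (eps1 - y/n) / (eps1 + eps2 - 1)

clamped to [0, 1]: an observed proportion below eps1 gives theta_hat = 0 and
one above 1 - eps2 gives theta_hat = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

VALID_CONTEXTS = ("CG", "CHG", "CHH", "pooled")


@dataclass(frozen=True)
class ContextCounts:
    """The binomial sufficient statistic for one locus and sequence context."""

    y: int
    n: int
    context: str = "pooled"

    def __post_init__(self) -> None:
        if not (0 <= self.y <= self.n):
            raise ValueError(f"need 0 <= y <= n, got y={self.y}, n={self.n}")
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"context must be one of {VALID_CONTEXTS}")

    @property
    def proportion(self) -> float:
        if self.n == 0:
            raise ValueError("proportion undefined at n = 0")
        return self.y / self.n


@dataclass(frozen=True)
class PointErrors:
    """Point estimates of the two conversion error rates.

    ``eps1`` — non-conversion: truly unmethylated read observed as methylated.
    ``eps2`` — false conversion: truly methylated read observed as unmethylated.
    The estimator requires eps1 + eps2 < 1 (otherwise observed and true
    methylation become anti-correlated and the correction is meaningless).
    """

    eps1: float = 0.0
    eps2: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.eps1 < 1.0 and 0.0 <= self.eps2 < 1.0):
            raise ValueError(f"error rates must lie in [0, 1): {self}")
        if self.eps1 + self.eps2 >= 1.0:
            raise ValueError(
                f"eps1 + eps2 must be < 1 for an identifiable correction: {self}"
            )

    def observed_proportion(self, theta: float) -> float:
        """Probability a read is observed unconverted given true level theta."""
        return theta * (1.0 - self.eps2) + (1.0 - theta) * self.eps1


@dataclass(frozen=True)
class MethylationEstimate:
    """Corrected methylation estimate with its clamping status."""

    theta_hat: float
    clamped: str  # none | at_zero | at_one
    y: int
    n: int
    errors: PointErrors

    @property
    def raw_proportion(self) -> float:
        return self.y / self.n


def log_likelihood(
    y: int, n: int, theta: float, errors: PointErrors = PointErrors()
) -> float:
    """Log of the error-augmented binomial likelihood at theta."""
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    if not (0 <= y <= n) or n < 1:
        raise ValueError(f"invalid counts y={y}, n={n}")
    p = errors.observed_proportion(theta)
    return float(stats.binom.logpmf(y, n, p))


def likelihood(
    y: int, n: int, theta: float, errors: PointErrors = PointErrors()
) -> float:
    """Error-augmented binomial likelihood Pr(y | n, theta, eps1, eps2).

    With eps1 = eps2 = 0 this is the plain binomial likelihood of the
    observed counts.
    """
    return float(np.exp(log_likelihood(y, n, theta, errors)))


def mle_theta(y: int, n: int, errors: PointErrors = PointErrors()) -> MethylationEstimate:
    """Closed-form maximum-likelihood estimate of true methylation level.

    The raw estimate (eps1 - y/n) / (eps1 + eps2 - 1) is clamped into [0, 1];
    the ``clamped`` flag records which boundary, if any, was hit. With zero
    error rates the estimate is exactly y/n.
    """
    if n < 1:
        raise ValueError("need at least one read (n >= 1)")
    if not (0 <= y <= n):
        raise ValueError(f"invalid counts y={y}, n={n}")
    p = y / n
    raw = (errors.eps1 - p) / (errors.eps1 + errors.eps2 - 1.0)
    if raw < 0.0:
        theta_hat, clamped = 0.0, "at_zero"
    elif raw > 1.0:
        theta_hat, clamped = 1.0, "at_one"
    else:
        theta_hat, clamped = raw, "none"
    return MethylationEstimate(
        theta_hat=theta_hat, clamped=clamped, y=y, n=n, errors=errors
    )


def pooled_estimate(
    counts: Sequence[ContextCounts], errors: PointErrors = PointErrors()
) -> MethylationEstimate:
    """Pool counts over loci, then correct once with a single error-rate pair.

    Summing reads across loci (e.g. the TEs of one family) before applying
    the closed-form estimator matches correcting the pooled proportion with
    one shared error rate; per-locus correction followed by averaging is
    available via :func:`mean_of_locus_estimates`.
    """
    if not counts:
        raise ValueError("no counts supplied")
    y = sum(c.y for c in counts)
    n = sum(c.n for c in counts)
    if n == 0:
        raise ValueError("zero pooled coverage")
    return mle_theta(y, n, errors)


def mean_of_locus_estimates(
    counts: Sequence[ContextCounts], errors: PointErrors = PointErrors()
) -> float:
    """Correct each locus separately and average the estimates (variant)."""
    ests = [mle_theta(c.y, c.n, errors).theta_hat for c in counts if c.n > 0]
    if not ests:
        raise ValueError("no loci with coverage")
    return float(np.mean(ests))
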