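"""Likelihood-based classification of locus methylation state.

Plants methylate cytosines in three sequence contexts (CG, CHG, CHH) through
distinct pathways, giving three canonical locus states:

* **um** — unmethylated: unconverted reads in every context are explained by
  non-conversion errors alone;
* **gbm** — gene-body-like: real methylation at CG sites only;
* **TEm** — TE-like: real methylation in all three contexts.

With false conversion assumed negligible, the evidence that a context's
unconverted proportion is error-only is

    f(p) = Binom(y; n, p) * BetaPDF(p; a, b)

and the evidence for more methylation than errors can explain is

    g(p) = Binom(y; n, p) * BetaCDF(p; a, b)

where Beta(a, b) is the fitted distribution of error rates. The beta CDF
factor vanishes when the unconverted proportion sits in the error
distribution's lower tail and saturates at one when it exceeds what errors
can account for. State likelihoods multiply the per-context factors:
L_um = f f f over (CG, CHG, CHH), L_gbm = g f f, L_TEm = g g g; posteriors
follow by normalisation.

Both f and g are evaluated at the continuity-corrected plug-in proportion
p~ = (y + 0.5) / (n + 1), which stays strictly inside (0, 1) even when
y = 0 or y = n, where the beta density degenerates. Fully integrated
variants (marginalising p over the error distribution) are available via
``evaluation="marginal"`` for sensitivity analysis; the integrated f is the
beta-binomial mass function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import integrate, stats
from scipy.special import logsumexp

from bsconv.error_profile import BetaErrorModel
from bsconv.estimation import ContextCounts

STATES = ("um", "gbm", "TEm")

Evaluation = Literal["plugin", "marginal"]


@dataclass(frozen=True)
class LocusContextData:
    """Per-context unconverted/total read counts for one locus."""

    locus_id: str
    counts_cg: ContextCounts
    counts_chg: ContextCounts
    counts_chh: ContextCounts

    @property
    def has_full_coverage(self) -> bool:
        """At least one aligned read in each sequence context."""
        return min(self.counts_cg.n, self.counts_chg.n, self.counts_chh.n) >= 1


@dataclass(frozen=True)
class StateCall:
    """Per-locus log-likelihoods, posteriors and hard call for the three states."""

    locus_id: str
    log_likelihoods: tuple[float, float, float]  # um, gbm, TEm
    posteriors: tuple[float, float, float]
    call: str  # um | gbm | TEm | undetermined

    @property
    def determinate(self) -> bool:
        return self.call in STATES


def _plugin_point(counts: ContextCounts) -> float:
    return (counts.y + 0.5) / (counts.n + 1.0)


def log_f_value(counts: ContextCounts, model: BetaErrorModel) -> float:
    """Log evidence that the context's counts arise from errors alone."""
    if counts.n < 1:
        raise ValueError("f undefined at n = 0")
    p = _plugin_point(counts)
    return float(
        stats.binom.logpmf(counts.y, counts.n, p)
        + stats.beta.logpdf(p, model.a, model.b)
    )


def log_g_value(counts: ContextCounts, model: BetaErrorModel) -> float:
    """Log evidence that the context carries more methylation than errors allow."""
    if counts.n < 1:
        raise ValueError("g undefined at n = 0")
    p = _plugin_point(counts)
    return float(
        stats.binom.logpmf(counts.y, counts.n, p)
        + stats.beta.logcdf(p, model.a, model.b)
    )


def f_value(counts: ContextCounts, model: BetaErrorModel) -> float:
    """Evidence density f(p~) = Binom(y; n, p~) * BetaPDF(p~; a, b)."""
    return float(np.exp(log_f_value(counts, model)))


def g_value(counts: ContextCounts, model: BetaErrorModel) -> float:
    """Evidence g(p~) = Binom(y; n, p~) * BetaCDF(p~; a, b)."""
    return float(np.exp(log_g_value(counts, model)))


def f_marginal(counts: ContextCounts, model: BetaErrorModel) -> float:
    """Integrated variant of f: the beta-binomial marginal of y.

    Integrating Binom(y; n, p) BetaPDF(p; a, b) over p gives exactly the
    beta-binomial pmf, evaluated in closed form.
    """
    if counts.n < 1:
        raise ValueError("f undefined at n = 0")
    return float(stats.betabinom.pmf(counts.y, counts.n, model.a, model.b))


def g_marginal(counts: ContextCounts, model: BetaErrorModel) -> float:
    """Integrated variant of g: quadrature of Binom(y; n, p) BetaCDF(p; a, b) dp."""
    if counts.n < 1:
        raise ValueError("g undefined at n = 0")
    y, n = counts.y, counts.n

    def integrand(p: float) -> float:
        return stats.binom.pmf(y, n, p) * stats.beta.cdf(p, model.a, model.b)

    value, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return float(value)


def _log_fg(
    counts: ContextCounts, model: BetaErrorModel, evaluation: Evaluation
) -> tuple[float, float]:
    if evaluation == "plugin":
        return log_f_value(counts, model), log_g_value(counts, model)
    if evaluation == "marginal":
        with np.errstate(divide="ignore"):
            return (
                float(np.log(f_marginal(counts, model))),
                float(np.log(g_marginal(counts, model))),
            )
    raise ValueError(f"unknown evaluation mode {evaluation!r}")


def classify_locus(
    data: LocusContextData,
    model_cg: BetaErrorModel,
    model_chg: BetaErrorModel | None = None,
    model_chh: BetaErrorModel | None = None,
    evaluation: Evaluation = "plugin",
) -> StateCall:
    """Call the methylation state of one locus from its per-context counts.

    A single error model may be shared across contexts (the default when
    only ``model_cg`` is given) or one model passed per context. Loci
    lacking coverage in any context are returned ``undetermined`` with NaN
    posteriors, as are exact posterior ties.
    """
    model_chg = model_chg or model_cg
    model_chh = model_chh or model_cg
    nan3 = (math.nan, math.nan, math.nan)
    if not data.has_full_coverage:
        return StateCall(data.locus_id, nan3, nan3, "undetermined")

    lf_cg, lg_cg = _log_fg(data.counts_cg, model_cg, evaluation)
    lf_chg, lg_chg = _log_fg(data.counts_chg, model_chg, evaluation)
    lf_chh, lg_chh = _log_fg(data.counts_chh, model_chh, evaluation)

    log_l = np.array([
        lf_cg + lf_chg + lf_chh,   # um
        lg_cg + lf_chg + lf_chh,   # gbm
        lg_cg + lg_chg + lg_chh,   # TEm
    ])
    if np.all(np.isneginf(log_l)):
        return StateCall(data.locus_id, tuple(log_l), nan3, "undetermined")

    posteriors = np.exp(log_l - logsumexp(log_l))
    posteriors /= posteriors.sum()
    best = int(np.argmax(posteriors))
    if np.sum(posteriors == posteriors[best]) > 1:
        return StateCall(data.locus_id, tuple(log_l), tuple(posteriors), "undetermined")
    return StateCall(
        locus_id=data.locus_id,
        log_likelihoods=tuple(float(v) for v in log_l),
        posteriors=tuple(float(v) for v in posteriors),
        call=STATES[best],
    )


def global_state_probabilities(
    calls: Sequence[StateCall],
) -> tuple[float, float, float]:
    """Mean posterior per state over determinate loci.

    The average posterior is the expected fraction of loci in each state,
    propagating per-locus uncertainty instead of counting hard calls.
    """
    post = np.array([c.posteriors for c in calls if c.determinate], dtype=float)
    if post.size == 0:
        raise ValueError("no determinate calls")
    means = post.mean(axis=0)
    return tuple(float(v) for v in means)


def collect_locus_data(
    records: Sequence,
    loci: Sequence[tuple[str, int, int, str]],
) -> list[LocusContextData]:
    """Aggregate per-site report records into per-locus, per-context counts.

    ``loci`` are ``(chrom, start, end, name)`` in 0-based half-open
    coordinates (BED convention); a 1-based site at ``pos`` belongs to a
    locus when ``start < pos <= end``.
    """
    acc: dict[str, dict[str, list[int]]] = {
        name: {"CG": [0, 0], "CHG": [0, 0], "CHH": [0, 0]}
        for _, _, _, name in loci
    }
    for rec in records:
        for chrom, start, end, name in loci:
            if rec.chrom == chrom and start < rec.pos <= end:
                acc[name][rec.context][0] += rec.meth_count
                acc[name][rec.context][1] += rec.coverage
    out = []
    for _, _, _, name in loci:
        by_ctx = acc[name]
        out.append(
            LocusContextData(
                locus_id=name,
                counts_cg=ContextCounts(*by_ctx["CG"], context="CG"),
                counts_chg=ContextCounts(*by_ctx["CHG"], context="CHG"),
                counts_chh=ContextCounts(*by_ctx["CHH"], context="CHH"),
            )
        )
    return out


def hard_call_fractions(calls: Sequence[StateCall]) -> tuple[float, float, float]:
    """Fraction of determinate loci hard-called to each state."""
    det = [c for c in calls if c.determinate]
    if not det:
        raise ValueError("no determinate calls")
    return tuple(sum(c.call == s for c in det) / len(det) for s in STATES)
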