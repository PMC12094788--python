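"""Simulation study of error-corrected methylation estimation.

Loci of 200 cytosines are sequenced at a grid of coverages; each locus
carries its own non-conversion rate drawn from a beta distribution, and each
read is observed unconverted with probability p = theta + (1 - theta) * eps1.
Methylation is then re-estimated under three scenarios:

* ``no_errors`` — error-free data, corrected with eps1 = 0 (the binomial
  sampling floor for the grid point);
* ``known_error`` — errored data, corrected with the realised mean of the
  drawn per-locus error rates;
* ``estimated_error`` — errored data, corrected with the beta mean
  a / (a + b), i.e. the rate one would estimate from control DNA.

Summaries per grid point and scenario are the mean absolute deviation from
the true level, the root-mean-square deviation, and the bias (mean of
estimate minus truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from bsconv.error_profile import BetaErrorModel
from bsconv.estimation import PointErrors, mle_theta

SCENARIOS = ("no_errors", "known_error", "estimated_error")

#: Default per-locus error-rate distribution fitted to chloroplast windows.
DEFAULT_ERROR_MODEL = BetaErrorModel(a=17.0, b=220.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Grid and generating parameters of the simulation study.

    Defaults model transposable-element-sized loci (200 cytosines over
    roughly 800 bp), true methylation 0.15 — realistic for TEs and
    deliberately close to typical non-conversion rates — coverages doubling
    from 1 to 32, pooling over 1, 10 or 100 loci, and per-locus error rates
    from Beta(17, 220) (mean ~7.2%).
    """

    n_cytosines_per_locus: int = 200
    coverages: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    n_loci_options: tuple[int, ...] = (1, 10, 100)
    theta: float = 0.15
    error_model: Optional[BetaErrorModel] = DEFAULT_ERROR_MODEL
    n_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cytosines_per_locus < 1 or self.n_reps < 1:
            raise ValueError("counts must be >= 1")
        if any(c < 1 for c in self.coverages) or any(
            m < 1 for m in self.n_loci_options
        ):
            raise ValueError("coverages and loci counts must be >= 1")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")


def draw_locus(
    theta: float,
    coverage: int,
    n_cytosines: int,
    error_model: Optional[BetaErrorModel],
    rng: np.random.Generator,
) -> tuple[int, int, float]:
    """Simulate one locus: (unconverted reads y, total reads n, drawn eps1).

    n = n_cytosines * coverage trials; y is a single binomial draw at
    p = theta + (1 - theta) * eps1, which is distributionally identical to
    per-read draws for exchangeable reads.
    """
    eps1 = float(error_model.rvs(1, rng)[0]) if error_model is not None else 0.0
    n = n_cytosines * coverage
    p = theta + (1.0 - theta) * eps1
    y = int(rng.binomial(n, p))
    return y, n, eps1


def estimate_scenario(
    loci: Sequence[tuple[int, int, float]],
    scenario: str,
    error_model: Optional[BetaErrorModel] = None,
) -> float:
    """Pool loci and apply the closed-form corrected estimator for one scenario.

    The correction rate is 0 (``no_errors``), the realised mean of the drawn
    per-locus rates (``known_error``), or the error model's mean
    (``estimated_error``). False conversion is taken as zero throughout.
    """
    if not loci:
        raise ValueError("no loci supplied")
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    y = sum(l[0] for l in loci)
    n = sum(l[1] for l in loci)
    if scenario == "no_errors":
        eps1 = 0.0
    elif scenario == "known_error":
        eps1 = float(np.mean([l[2] for l in loci]))
    else:
        # without an error model the estimated rate is trivially zero
        eps1 = error_model.mean if error_model is not None else 0.0
    return mle_theta(y, n, PointErrors(eps1=eps1)).theta_hat


def run_experiment(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full coverage x loci x scenario x replicate grid.

    Returns the per-replicate estimates (long format) and the per-grid-point
    summary. Each replicate draws an error-free and an errored data set; the
    ``known_error`` and ``estimated_error`` scenarios share the errored set
    so their difference isolates the effect of error-rate uncertainty.
    Fully deterministic given ``config.seed``: every (coverage, n_loci, rep)
    cell has its own child stream spawned from the root seed.
    """
    rows = []
    for coverage in config.coverages:
        for n_loci in config.n_loci_options:
            # grid-point stream keyed by (coverage, n_loci): reproducible
            # even when only part of the grid is run
            cell_rngs = [
                np.random.default_rng(s)
                for s in np.random.SeedSequence(
                    entropy=config.seed,
                    spawn_key=(int(coverage), int(n_loci)),
                ).spawn(config.n_reps)
            ]
            for rep, rng in enumerate(cell_rngs):
                clean = [
                    draw_locus(config.theta, coverage,
                               config.n_cytosines_per_locus, None, rng)
                    for _ in range(n_loci)
                ]
                # without an error model the "errored" data set is the clean
                # one and all three scenarios coincide exactly
                errored = clean if config.error_model is None else [
                    draw_locus(config.theta, coverage,
                               config.n_cytosines_per_locus,
                               config.error_model, rng)
                    for _ in range(n_loci)
                ]
                estimates = {
                    "no_errors": estimate_scenario(clean, "no_errors"),
                    "known_error": estimate_scenario(errored, "known_error"),
                    "estimated_error": estimate_scenario(
                        errored, "estimated_error", config.error_model
                    ),
                }
                for scenario, est in estimates.items():
                    rows.append(
                        {
                            "rep": rep,
                            "coverage": coverage,
                            "n_loci": n_loci,
                            "scenario": scenario,
                            "estimate": est,
                        }
                    )
    estimates_df = pd.DataFrame(rows)
    summary_df = summarise(estimates_df, config.theta)
    return estimates_df, summary_df


def summarise(estimates: pd.DataFrame, theta: float) -> pd.DataFrame:
    """Per (coverage, n_loci, scenario): mean |dev|, RMS deviation and bias."""
    dev = estimates["estimate"] - theta
    frame = estimates.assign(_dev=dev)
    grouped = frame.groupby(["coverage", "n_loci", "scenario"], sort=True)
    out = grouped["_dev"].agg(
        mean_deviation=lambda d: float(np.mean(np.abs(d))),
        rms_deviation=lambda d: float(np.sqrt(np.mean(d**2))),
        bias="mean",
    )
    return out.reset_index()
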