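# Methods

## Error-augmented binomial model

A locus (or window, or pooled set of loci) contributes the sufficient
statistic (y, n): of n reads covering its cytosines, y were observed
unconverted. Two error rates enter the observation model:

* ε₁, the non-conversion rate — a truly unmethylated cytosine observed as
  cytosine;
* ε₂, the false-conversion rate — a truly methylated cytosine observed as
  thymine.

A read is observed unconverted with probability
p = θ(1 − ε₂) + (1 − θ)ε₁ where θ is the true methylation level, so
y ~ Binomial(n, p) and the MLE is the linear back-transformation
θ̂ = (ε₁ − y/n)/(ε₁ + ε₂ − 1). The estimator requires ε₁ + ε₂ < 1, which
`PointErrors` enforces at construction — beyond that boundary observed and
true methylation become anti-correlated and the correction is meaningless.
Observed proportions below ε₁ (or above 1 − ε₂) would map outside [0, 1];
they are clamped, and the estimate carries an `at_zero` / `at_one` flag so
downstream code can see boundary cases. Clamped estimates are retained in
all summaries: they are the estimator's actual output, and dropping them
would bias the very comparisons the simulation study makes. ε₂ defaults to
0 everywhere (false conversion is rarely measurable without a fully
methylated spike-in control) but the API carries both rates.

Likelihoods are computed in log space (`scipy.stats.binom.logpmf`) and
exponentiated only on demand.

## Beta model of error-rate variation

Non-conversion rates vary several-fold between genomic windows of control
DNA, far beyond binomial noise. The package models the window-level rate as
Beta(a, b) and fits (a, b) by method of moments from the sample mean and
unbiased (m − 1 denominator) sample variance of window rates. The moment
inversion requires σ² < μ(1 − μ); violations raise rather than silently
clamp, since they mean the data are incompatible with any beta
distribution.

One caveat the moment fit inherits from its inputs: the observed
between-window variance is the true rate variance *plus* the binomial
sampling variance of each window's rate estimate (≈ mean r(1 − r)/nᵢ). With
few reads per window this inflates σ² and shrinks the fitted shape
parameters while leaving the mean intact — e.g. at 500 reads/window the
sampling component is ≈ 1.3 × 10⁻⁴ against a true beta variance of
≈ 2.8 × 10⁻⁴ for Beta(17, 220), biasing â from 17 towards ≈ 11.
`fit_error_model_from_windows(..., correct_binomial_noise=True)` subtracts
the estimated sampling component before inversion; the default is the plain
fit, appropriate when windows hold thousands of reads (typical control
coverage) and matching the straightforward windowed-moments procedure the
model mirrors.

The variance-inflation diagnostic compares the observed between-window
variance with a simulated binomial null: each window's unconverted count is
redrawn binomially at the global mean rate with its observed coverage
(default 200 simulated window sets, seeded). An analytic variant uses
E[sample variance] = mean g(1 − g)/nᵢ, exact for independent windows with a
common mean, and serves as a cross-check of the simulated null.

## Read-level diagnostics

Per-read methylation calls are taken from Bismark-convention SAM tags: XM
(call string; uppercase = unconverted; Z/X/H/U for CG/CHG/CHH/unknown
context), XR/XG (read/genome conversion), with the strand class mapped as
(CT,CT)→OT, (CT,GA)→CTOT, (GA,CT)→OB, (GA,GA)→CTOB. Reads without
cytosines are excluded from read-level statistics; unknown-context calls
count towards per-read fractions and positional profiles but not towards
per-context counts. Reads split into fully converted, partially
unconverted, and fully unconverted — the two unconverted classes point to
two distinct error mechanisms (whole-fragment displacement from an adaptor
nick vs displacement downstream of an internal nick), and the positional
profile per strand class makes the internal-nick mechanism visible as a
rise in unconverted rate towards the 3′ end.

## State classification

Three locus states: unmethylated (um), gene-body-like (gbm; CG-only
methylation) and TE-like (TEm; methylation in all contexts). Per context
the error-only evidence is f(p) = Binom(y; n, p)·BetaPDF(p; a, b) and the
methylated evidence g(p) = Binom(y; n, p)·BetaCDF(p; a, b); state
likelihoods are L_um = f·f·f, L_gbm = g·f·f, L_TEm = g·g·g over
(CG, CHG, CHH), normalised into posteriors. ε₂ is taken as zero here.

Numerical choices:

* **Evaluation point.** f and g are functions of the observed proportion,
  which degenerates at y = 0 and y = n (the beta density is 0 or ∞ there).
  Both are evaluated at the continuity-corrected p̃ = (y + ½)/(n + 1),
  strictly inside (0, 1) for all counts. Fully integrated alternatives
  (`evaluation="marginal"`) marginalise p over the error distribution — the
  integrated f is exactly the beta-binomial pmf, the integrated g is done
  by quadrature — and agree with the plug-in rule on all tested calls;
  plug-in is the default for speed and transparency.
* **Log space.** State likelihoods are log-sums of per-context terms and
  posteriors come from a log-sum-exp normalisation, so simultaneous
  underflow of all three likelihoods cannot occur for finite counts.
* **Degenerate input.** A locus lacking coverage in any context is
  `undetermined` (NaN posteriors), mirroring the requirement of at least
  one aligned read per context. Exact posterior ties are also
  `undetermined` — a measure-zero event not worth an arbitrary ordering.
* **Per-context models.** Contexts differ in their association with
  non-conversion, so `classify_locus` accepts one error model per context;
  the default shares a single control-fitted model across contexts.

The global probability of state i is the mean posterior over determinate
loci — the expected state fractions with per-locus uncertainty propagated —
and agrees with hard-call fractions within 0.05 on fixtures at moderate
coverage.

## Simulation study

`run_experiment` simulates loci of 200 cytosines (the scale of a typical
transposable element) at coverages 1–32 pooled over 1, 10 or 100 loci, true
methylation θ = 0.15 (TE-like, deliberately close to realistic error
rates), per-locus ε₁ ~ Beta(17, 220) (mean ≈ 7.2%), 200 replicates per grid
point. A single binomial draw per locus at p = θ + (1 − θ)ε₁ is
distributionally identical to per-read draws for exchangeable reads.
Estimation scenarios: `no_errors` (error-free draws, no correction),
`known_error` (errored draws corrected with the realised mean of the drawn
per-locus rates — correcting pooled counts once, as pooling implies), and
`estimated_error` (corrected with the beta mean a/(a + b), i.e. the rate
one would carry over from control DNA). Without an error model the errored
data reuse the clean draws so all scenarios coincide exactly.

Summaries per grid point: mean absolute deviation |θ̂ − θ| (with RMS
deviation alongside), and bias (mean θ̂ − θ). Corrected scenarios are
unbiased (|bias| < 0.01 from coverage 16 × 10 loci up), and deviation
falls with total read count along each grid axis. One structural feature:
for `estimated_error` at a single locus, deviation floors at the
locus-to-locus error-rate spread (≈ 0.014 here) no matter the coverage —
pooling loci, not deepening coverage, is what averages that uncertainty
away. Deviation is therefore *not* monotone in the coverage × loci product.

Randomness: every (coverage, n_loci) grid cell derives per-replicate
streams from the root seed via `SeedSequence(entropy=seed, spawn_key=...)`,
so results are reproducible cell-by-cell under partial execution.

## Synthetic fixtures

The generators emulate the data-generating processes the framework targets,
with recorded truth:

* **Control report** — per-window ε from the beta model, per-site binomial
  counts; sites evenly spaced, cycling contexts. Emulates an unmethylated
  control genome with spatially varying error rates.
* **State report** — loci in known states; per locus × context one ε draw
  and binomial counts at θ + (1 − θ)ε. Generation rejects methylated θ at
  or below the error-model mean, where states are unidentifiable in
  principle.
* **Tagged reads** — the nick model: with probability `q_full` the whole
  read is unconverted (adaptor nick), with `q_nick` a single internal nick
  at a uniform offset leaves everything downstream unconverted
  (one nick per read suffices: additional nicks are indistinguishable from
  the most 5′ one), otherwise each cytosine fails conversion independently
  at a small residual rate. A `gc_biased_nicks` flag weights nick positions
  towards cytosines, off by default. Default mixture 0.15/0.15 is
  illustrative; real libraries vary.

What the fixtures do **not** emulate: bisulphite chemistry, PCR
duplicates, quality-score decay, the 5-bp periodicity seen on bottom
strands in some libraries, paired-end overlap, or any real genome's context
composition. Passing recovery tests on fixtures therefore demonstrates the
statistical machinery is self-consistent under its own assumptions — not
that those assumptions exhaust real libraries, where error rates correlate
with GC content and strand in ways the single shared beta model averages
over.

## Problem sizes

Defaults throughout are desk-scale: 200-window controls at coverage 50,
30–60-locus state reports, a few thousand reads for read-level statistics,
and the full 6 × 3 × 3 × 200 simulation grid, which completes in about a
second. Larger runs only sharpen the same estimates.
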