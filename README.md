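# bsconv

Statistical modelling and correction of cytosine **non-conversion errors**
in bisulphite sequencing.

Bisulphite treatment converts unmethylated cytosines to thymine; methylated
cytosines stay cytosine, so the ratio of C to T reads at a genomic cytosine
estimates its methylation level. Tagmentation-based library protocols that
repair the transposase gap by strand displacement with methylated dCTPs
leave a substantial rate of *non-conversion* errors — truly unmethylated
cytosines that read back as cytosine — inflating apparent methylation by
several percent and varying systematically along the genome. `bsconv` is for
anyone analysing such libraries (plant epigenomics in particular, where CHG
and CHH methylation rule out simple read filtering): it profiles the errors
on known-unmethylated control DNA, models them, and corrects downstream
methylation estimates and state calls.

## The model

Of *n* reads covering the cytosines of a locus, *y* are observed
unconverted. With non-conversion rate ε₁ and false-conversion rate ε₂, a
read is observed unconverted with probability

p = θ(1 − ε₂) + (1 − θ)ε₁,

where θ is the true methylation level, giving the binomial likelihood
Pr(y | θ) = C(n, y) pʸ(1 − p)ⁿ⁻ʸ and the closed-form MLE

θ̂ = (ε₁ − y/n) / (ε₁ + ε₂ − 1),

clamped to [0, 1]. Error rates vary along the genome; their distribution
across windows of control DNA is modelled as Beta(a, b), fitted by method
of moments from the sample mean μ and variance σ² of window rates:

â = μ(μ(1 − μ)/σ² − 1),  b̂ = (1 − μ)(μ(1 − μ)/σ² − 1).

For state classification, the evidence that a context's counts are
error-only is f(p) = Binom(y; n, p)·BetaPDF(p; a, b), and the evidence for
real methylation is g(p) = Binom(y; n, p)·BetaCDF(p; a, b). A locus is
scored as unmethylated (L_um = f·f·f over CG, CHG, CHH), gene-body-like
(L_gbm = g·f·f) or TE-like (L_TEm = g·g·g), with posteriors by
normalisation.

## Worked example

Generate an unmethylated control with window-varying error rates, profile
it, fit the error model, and classify loci of known state:

```
bsconv make-fixtures control --n-windows 200 --coverage 50 --seed 5 --out-dir fx
bsconv make-fixtures states --coverage 50 --seed 5 --out-dir fx
bsconv profile --report fx/control_report.tsv --region ctrl:1-30000 --out-dir prof
bsconv fit-errors --report fx/control_report.tsv --region ctrl:1-30000 --out-dir fit
bsconv classify --report fx/state_report.tsv --loci fx/loci.bed \
    --control-report fx/control_report.tsv --control-region ctrl:1-30000 \
    --out-dir calls
```

This prints, for example:

```
overall non-conversion rate: 7209/100000 = 0.072090
variance inflation vs binomial null: 2.52
beta error model: a = 14.2231, b = 183.0733 (mean error rate 0.0721)
global state probabilities: um 0.327, gbm 0.339, TEm 0.334 (model a=14.223, b=183.073)
```

Read: the control shows a 7.2% overall non-conversion rate whose
between-window variance is 2.5× what binomial sampling alone would give —
the signature of genuinely varying error rates — and the fitted beta model
has mean 0.072 (the fitted shape parameters sit below the generating
(17, 220) because sampling noise adds to the window variance; see
`docs/methods.md`). Classifying 30 loci generated in equal numbers of the
three states recovers the uniform mixture; `calls/state_calls.tsv` holds
the per-locus posteriors and hard calls.

The simulation study (`bsconv simulate --out-dir sim`) quantifies how well
the corrected estimator recovers a true methylation level of 0.15 across a
coverage × loci grid under beta-distributed errors; its summary table shows
the corrected scenarios unbiased (|bias| < 0.01 at coverage ≥ 16 with
≥ 10 loci) while deviation is driven by total read count.

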