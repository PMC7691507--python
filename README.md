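# driftlik

Distinguishing natural selection from random genetic drift in
evolve-and-resequence experiments with relaxed selection.

When artificial selection on a trait is suspended, allele frequencies at
the loci that responded to selection keep moving — by natural selection,
by random genetic drift, or both.  `driftlik` implements the analysis
that separates these forces for pooled-sequencing allele-frequency time
series: it computes, for every biallelic site, the exact probability of
the observed frequency shift under a pure Wright–Fisher drift model, and
asks whether a set of candidate variants is collectively less compatible
with drift than random, putatively neutral sites are.

It was built for a fly sleep experiment — six populations (two previously
selected for short sleep, two for long sleep, two unselected controls)
founded from an outbred population, sequenced as pools at the end of
artificial selection (generation 12) and after 63 further generations of
relaxed selection (generation 75), with a variance effective population
size of 2Ne = 84 allele copies — but every design parameter is
configurable.

## The model

Under a Wright–Fisher model with constant size 2Ne, the copy count of an
allele evolves by binomial resampling each generation:
k₁ ~ Binomial(2Ne, p₀) with p₀ = k₀/2Ne.  Over G generations the copy
count follows a compound (mixture) distribution, obtained by iterating
the binomial transition; `driftlik` computes it exactly as G
matrix–vector products with the (2Ne+1)×(2Ne+1) one-step transition
matrix, and also by Monte-Carlo simulation (the two agree to small
total-variation distance).  X-linked sites use Ne copies instead of 2Ne.
The frequency variance after G generations has the closed form
p₀(1−p₀)(1−(1−1/2Ne)^G), which the exact distribution reproduces to
1e−10.

Each site contributes a log-likelihood log L₁₂(p₇₅): the exact drift mass
on the copy count nearest the observed end frequency, started from the
copy count nearest the observed start frequency.  Sites fixed or lost and
unchanged have likelihood one; sites that merely *appear* fixed (read
frequency within 0.005 of a boundary) but shifted are restarted from 0.99
or 0.01 and flagged.  Frequencies are oriented to each site's minor
allele as defined in the founder (generation 0) population, and shifts
are classed as moving towards the major or towards the minor allele.

The observed statistic — the mean log-likelihood of the variant set (126
sites in the default design) — is located within a null distribution of
mean log-likelihoods from 1000 random background-site sets matched in
number and per-chromosome composition.  A variant mean in the far lower
tail of the null indicates shifts too improbable for drift alone, i.e.
natural selection.

A separate module applies the de novo mutation filter cascade: exclusion
of known catalog variants, caller-quality ≥ 124, total reads in
[40, 226], MaxQual ≥ 426, privacy (present in both DNA samples of exactly
one population), and absence from all prior-study generations.

Because the original raw sequence data are not needed to exercise any of
this, the package ships a synthetic-experiment generator that emulates
the whole design — drift with optional genic selection, pooled read
sampling with a negative-binomial depth model, and injected de novo
mutations straddling every filter threshold — with complete ground truth.

## Worked example

```bash
driftlik all --seed 1 --outdir demo --n-sets 1000
```

generates a synthetic experiment under the default selected design
(relaxed-phase selection s = −0.1 against the short-sleepers' minor
alleles, neutral long/control populations), runs the drift test and the
de novo cascade.  `demo/nulltest/summary.json` then contains, per
population, entries like:

```
"short1":   "towards_major": {"observed_mean": -4.019, "lower_tail_fraction": 0.0,   "inside_95pct": false}
"control1": "towards_major": {"observed_mean": -1.733, "lower_tail_fraction": 0.538, "inside_95pct": true}
```

The short-sleeper variant mean (−4.02) lies below every one of the 1000
neutral-set means (lower-tail fraction 0.0, outside the null's 95% band):
its towards-major shifts are collectively too improbable for drift, the
signature of natural selection.  The control population's mean sits in
the middle of its null (tail fraction 0.54): indistinguishable from
drift.  `demo/denovo/denovo_summary.json` reports the 30 injected de novo
candidates that survive the cascade, split SNP/indel per population.

Library use mirrors the CLI:

```python
from driftlik import PopulationSpec, ShiftObservation, shift_loglikelihood
spec = PopulationSpec(copies_autosome=84, n_steps=63)
shift_loglikelihood(ShiftObservation("site", "2L", 0.62, 0.25), spec).loglik
# -4.9838...
```

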