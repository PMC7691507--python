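# Methods

## Drift model

The core object is the exact distribution of a biallelic allele's copy
count under the Wright–Fisher model at constant effective size.  A
population is a pool of `M` allele copies — `M = copies_autosome = 2Ne`
for autosomal sites and `M = copies_x = Ne` for X-linked sites (default
84 and 42, the variance effective size estimated for the six fly
populations the package was designed around, maintained at 25 pairs of
parents per generation).  One generation is a binomial resampling step:
given `k` copies now, the next generation holds `k' ~ Binomial(M, k/M)`.
Iterating over `G` generations yields a compound (mixture) distribution
over the states `0..M`; loss (0) and fixation (M) are absorbing.

`compound_distribution` evaluates this exactly by `G` successive
matrix–vector products with the one-step transition matrix
`T[j, k] = Binom(M, j/M).pmf(k)` applied to the point mass at the start
count.  This is mathematically identical to the nested-sum recursion for
the G-generation distribution but costs O(G·M²) instead of exponential
work.  The implementation is validated against two independent routes:
`numpy.linalg.matrix_power` of the same transition matrix (agreement to
1e−10 over randomised `M ≤ 100, G ≤ 100` grids) and Monte-Carlo
simulation (`simulate_trajectories`; total-variation distance < 0.02 at
100,000 replicates for M = 84).  Exact invariants — unit mass, the
martingale property E[p_G] = p₀, the closed-form variance
p₀(1−p₀)(1−(1−1/M)^G), and monotone growth of the absorbed mass — are
enforced by property tests.

Observed read frequencies do not live on the copy-count lattice; they are
mapped to the nearest integer count, ties rounding half up.  This mapping
is the package's own convention; the model itself is only defined on
integer copies.

`n_steps` defaults to 63, the number of generation transitions between
the two sequenced time points (generation 12 through generation 75).  It
is deliberately exposed as a parameter rather than hard-coded: the span
is sometimes described as 62 generations of relaxed selection, and a user
who prefers that reading can set it.

## Shift likelihoods and boundary rules

A site's evidence is `log L₁₂(p₇₅)`: the log of the exact drift mass on
the lattice point nearest the end frequency, starting from the lattice
point nearest the start frequency, over `n_steps` transitions.  Natural
logarithms are used throughout.

Boundary handling follows three rules:

* exactly fixed/lost and unchanged → probability one, log-likelihood 0
  (drift cannot move an absorbed allele);
* read frequency within 0.005 of a boundary *but shifted* → the site
  cannot truly have been absorbed (pooled sequencing hides rare alleles),
  so the start is reset to the nearest interior grid frequency (0.01 or
  0.99) and the result flagged `boundary_adjusted`;
* any remaining zero or underflowing mass → floored at log(1e−300), so
  set means stay finite.  The flag distinguishes the reset rule from the
  floor.

Shifts are classified by the direction of the oriented minor-allele
frequency: towards the major allele (decrease), towards the minor allele
(increase), or unchanged.  Exact ties form their own "unchanged" class
and belong to neither direction stratum; they still count in the
all-sites mean.

## Resampling null

The set-level statistic is the mean log-likelihood of the variant set.
Its null is built by drawing `n_sets` random sets of background sites
matched exactly in number and per-chromosome count to the variant set
(1000 sets of 126 sites in the default design), without replacement
within a set and independently across sets.  Background sites are all
biallelic sites passing the coverage filters that are not variants of
interest; no frequency matching is applied by default (an optional flag
adds it), since the design matches number and chromosome only.
Direction-stratified means are computed within each sampled set, so each
direction class is located in a null of like-classified background sites.

`locate_observed` reports the lower-tail fraction (share of null means at
or below the observed mean — small values indicate selection), a
z-like standardised offset, and whether the observed mean falls inside
the null's empirical 2.5–97.5 percentile band.  Calibration measured on
fully neutral synthetic experiments: with 1000 null sets the 95% band
covers the observed mean in ≈94% of experiments, and the lower-tail
fraction is uniform.  Roughly one point of the shortfall from the nominal
95% is intrinsic to empirical percentile bands at finite set counts (the
band endpoints interpolate order statistics), and the remainder to the
left skew of the per-site log-likelihood distribution interacting with
the finite background pool; both effects are visible in a pure
resampling mock without any population genetics.  At 200 null sets the
coverage drops to ≈92%, which is why the full 1000-set design is used in
the calibration checks.

## Coverage filter, orientation, intervals

Site tables are one row per site × population × generation × DNA sample.
The two samples per population are summed after a per-sample coverage
filter keeping `10 ≤ coverage < 226` (the upper bound is the 99.5% point
of the coverage distribution and is itself excluded).  The minor allele
is fixed per site as the least frequent allele in the founder
(generation 0) pool, ties breaking deterministically to the alternate
allele with a flag; all later frequencies are expressed for that allele.
Credible intervals for read proportions are highest-posterior-density
intervals of the Beta posterior with a Jeffreys Beta(1/2, 1/2) prior
(configurable); boundary-mode posteriors give one-sided intervals, and
interior-mode intervals minimise width over the lower tail probability.

## De novo cascade

Candidates pass four independent, commuting predicates: not in the known
catalog (exact chrom/pos/ref/alt match); quality score ≥ 124, total reads
in the inclusive range [40, 226], MaxQual ≥ 426 (all three configurable —
they gate two different caller score distributions and are treated as
independent); private to one population (≥ 1 alternate read — the
configurable presence threshold — in *both* DNA samples of exactly one
population, none elsewhere); and absent from every prior-study
generation.  Note the de novo read bounds are inclusive while the
analysis coverage filter's upper bound is exclusive; each follows the
literal definition of its own step.  Attrition reports charge each
removal to the first failing filter (so removals plus survivors equal the
input) while reason codes list every failing filter; SNPs and indels are
tallied separately.

## Synthetic experiments

The generator emulates the study's downstream data products, not its raw
reads.  Defaults: 126 variant sites and 5000 background sites placed on
arms 2L/2R/3L/3R/X in proportion to dm6 arm length; founder minor-allele
frequencies uniform on [0.05, 0.5], assigned to ref or alt at random;
2Ne = 84 (Ne = 42 on X); 12 artificial-selection transitions followed by
63 relaxed ones; two 30-fly DNA samples per population per generation
with negative-binomial depth (mean 100, dispersion 20 — nearly all
coverage inside the 10/226 gates) and zero sequencing error.

Selection is a per-generation deterministic genic (haploid-equivalent)
update `p' = p(1+s)/(1+ps)` on the founder-minor allele before binomial
resampling; with `s = 0` this reduces exactly to the drift model, which
is the basis of the calibration tests.  Genic selection was chosen over a
diploid fitness scheme because the analysis operates on allele copies,
not genotypes.  The default coefficients emulate the study qualitatively:
artificial phase s = +0.25 (short) / −0.25 (long) / 0 (control) on the
minor allele, relaxed phase s = −0.1 (short) / 0 / 0 — i.e. natural
selection pushing the short-sleepers' variants back towards the major
allele, the pattern the analysis is designed to detect.  The artificial
phase is emulated by directional s rather than truncation selection on a
phenotype, since no genotype–phenotype map is modelled.
`ExperimentConfig.neutral()` zeroes every coefficient for calibration
work.

What the generator deliberately does not model: linkage between sites
(the likelihood assumes independent sites, so the generator matches that
assumption — passing tests say nothing about LD-induced miscalibration
on real data), phenotypes, sex-specific X transmission, and
alignment/calling artefacts other than a flat error rate.  Injected de
novo candidates are synthetic constructions whose attributes straddle
every filter threshold (quality 123/124, MaxQual 425/426, reads
39/40/226/227, one-sample and two-population privacy violations,
catalog and prior-study hits) with a truth table of expected fates.

Ground truth records the alt-allele frequency of every site at the three
sequenced generations, full relaxed-phase trajectories for the variant
sites, all selection coefficients, and the de novo truth.  All
randomness flows from one seeded generator, making outputs byte-identical
for identical config + seed (the run manifest's wall-clock timestamp is
the single documented exception).

## Problem sizes used in the checks

The calibration study uses 200 neutral experiments at the full default
design with 1000 null sets each; the power study uses 100 selected
experiments with 200 null sets (the selection signal — median lower-tail
fraction 0 on the towards-major stratum — does not need finer null
resolution); the analytic-vs-simulation comparison uses 100,000
replicates.  These sizes were chosen so the whole suite and the
acceptance script each complete in minutes on a single CPU while keeping
Monte-Carlo error well below the asserted margins.

## Known limitations

* The drift model is strictly neutral, constant-size, and biallelic; no
  mutation, migration, or selection enters the likelihood.
* Pool-seq read noise enters through the lattice rounding of observed
  frequencies, not as an explicit sampling layer in the likelihood; very
  low coverage therefore degrades the test in ways the boundary rules
  only partially absorb.
* The significance annotation for per-site frequency change is a
  two-sided Fisher exact test on the read-count table, provided as an
  annotation only; it is not part of the drift test.
* Sites are treated as independent; correlated (linked) sites make the
  effective variant-set size smaller than its nominal count.
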