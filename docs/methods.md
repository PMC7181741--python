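# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the limitations of `admixsel`. It is written for a reader who
wants to know exactly what each statistic computes and what the test suite
does and does not demonstrate.

## Setting

The package analyses a two-way admixed population (the running example is an
Austronesian-speaking population from the western Solomon Islands) whose
genome is a mosaic of two ancestries: a Papuan-related component (proxied by
a lowland New Guinea panel) and an Asian-related component (proxied by a Han
Chinese or Taiwanese panel). Four questions are addressed:

1. Did admixture happen? (f3 three-population test)
2. In what proportions? (F4-ratio; genome-wide mean of local ancestry)
3. When? (exponential decay of admixture LD)
4. Did post-admixture selection distort local ancestry anywhere?
   (ancestry-excess outlier scan against a neutral coalescent null;
   corroborating EHH/iHS scan in the unadmixed source population)

## f-statistics (`fstats`)

For sample alt-allele frequencies `a, b, c` of populations A, B, C:

* `f3(C; A, B)` averages `(c - a)(c - b) - c(1 - c)/(n_C - 1)` over variants,
  where `n_C` is the number of non-missing alleles in C. The subtracted term
  removes the upward bias contributed by binomial sampling noise in `c`; it
  is what makes f3 of an unadmixed target non-negative in expectation. A
  significantly negative f3 means no tree can place C relative to A and B —
  the signature of admixture. The test is one-tailed, significant at
  Z < −2.33 (1% level).
* `f4(A, B; C, D)` averages `(a - b)(c - d)`; no correction is needed because
  the four sampling errors are independent.
* The F4-ratio `alpha = f4(Asian, Out; Admixed, Papuan) /
  f4(Asian, Out; AsianSister, Papuan)` estimates the Asian-related ancestry
  fraction. It is valid when the sister population splits from the Asian
  source lineage no earlier than the admixture pulse contribution.

Standard errors are leave-one-block-out jackknives over contiguous blocks
(default 5 Mb, ~5 cM — above the LD scale of array data, so block deletions
are approximately independent). Variants with any undefined frequency among
the populations of a statistic are skipped per-statistic, so SNP counts can
differ between statistics on the same dataset. The F4-ratio SE jackknifes
the ratio itself (both f4 sums recomputed per deleted block).

These are plain (non-heterozygosity-normalized) f-statistics. Exact numeric
parity with other f-statistic implementations is not claimed; the contract,
enforced by tests, is recovery of known truth on synthetic data.

## Admixture dating (`admix_dating`)

A single admixture pulse T generations ago creates LD between variant pairs
proportional to `exp(-T d)` at genetic distance `d` Morgans. The weighted-LD
statistic bins intra-chromosome pairs by distance (0.1 cM bins to 20 cM) and
computes per bin

    A(d) = sum_ij w_i w_j rho_ij / sum_ij |w_i w_j| ,

with `w = a - b` the panel frequency difference and `rho` the sample
correlation of dosages in the admixed population. `A(d)` is invariant to
swapping the panels (weights negate pairwise). Fitting
`A(d) = A0 exp(-n d/100) + c` (d in cM) by least squares returns `n`, the
generations since admixture; years use a 30-year generation time.

The fit starts at 0.5 cM by default: shorter distances are contaminated by
background LD that predates admixture. The normalized-correlation form is a
package choice — the weighted-LD literature contains several closely related
statistics, and the contract here is recovery of a known pulse age on tract
simulations (tests demand ±20% at T = 77 and proportionality when T
doubles), not parity with any specific tool.

## Local ancestry (`local_ancestry`)

A 3-state HMM on unphased genotypes of admixed individuals. The hidden state
is the unordered ancestry pair {AA, PA, PP}; the prior is Hardy–Weinberg in
the mixture proportion m, ((1−m)², 2m(1−m), m²). Between consecutive
variants at genetic distance d Morgans each of the two chromosomes switches
ancestry with probability `1 − exp(−T d)` into the stationary draw (P with
probability m); the diploid transition matrix is the product of the two
independent chromosome processes. The emission of genotype g given the state
convolves two Bernoulli allele draws from the pseudocount-smoothed panel
frequency of the relevant ancestry (pseudocount 0.5 per allele — a
Jeffreys-style shrinkage that keeps panel-fixed sites from producing zero
likelihoods). Missing genotypes emit likelihood 1. Forward–backward runs in
scaled arithmetic per chromosome; the per-site Papuan dosage is
`2 P(PP) + P(PA)`. EM re-estimates only m (as mean dosage / 2 over all sites
and individuals, 20 steps by default); T stays a user setting, mirroring
fixed-generations runs at T ∈ {50, 77, 100, 150}.

This deliberately replaces two-layer haplotype-cluster local-ancestry models
with a panel-frequency HMM. The estimand the downstream scan needs is the
posterior ancestry dosage, and on tract simulations with known truth the
HMM recovers it essentially unbiasedly (truth–posterior correlation > 0.9,
genome-wide mean within ±0.03 of the true m under study conditions). What
the panel-frequency emission does *not* reproduce is the long smooth
plateaus a haplotype-cluster model produces; see "Known limitations".

## Ancestry-excess scan (`ancestry_scan`)

The population mean track (per-variant mean of dosage/2) is summarized by
its genome-wide mean and population SD (denominator N; immaterial at ~10^5
positions but fixed). Positions strictly beyond mean ± 2 SD / ± 3 SD are
flagged; maximal runs of consecutive same-chromosome flagged positions form
regions (gap tolerance 0; singleton runs are zero-length regions, since
length is end − start in bp with 1-based inclusive coordinates). Grubbs'
test on the track is reported for comparability but its nominal p-value
assumes independent observations, which an ancestry track violates
massively; the calibrated test is the simulation null. The null thresholds
are computed from the simulated tracks themselves, and null regions are
called per simulation window (windows are independent, regions never span
windows).

## Selection scan (`selection_scan`)

EHH at flank x is the probability that two random carrier haplotypes of the
core allele are identical from the core out to x, computed by prefix-group
counting (`sum n_h(n_h−1) / (n_c(n_c−1))`). iHH integrates EHH by the
trapezoid rule over genetic distance, each side truncated at the first
flank whose EHH drops below 0.05 (that trapezoid is included); cores whose
EHH reaches a chromosome edge while still above the cutoff are flagged and
excluded from standardization rather than extrapolated. The unstandardized
score `ln(iHH_ancestral / iHH_derived)` is standardized to zero mean and
unit SD within 2%-wide derived-allele-frequency bins (bins with fewer than
10 cores merge with a neighbor), and the two-sided p-value is `2 Φ(−|iHS|)`.
Haplotypes with a missing call in the extended window are dropped from the
homozygosity count at that and further flanks. When no genetic map is
given, physical positions are converted at 1 cM = 1 Mb.

## Synthetic data (`synthetic_data`)

Two generators, used both as pipeline inputs and as test oracles.

**Coalescent windows.** msprime simulates independent 2 Mb windows under
the three-population history: one ancestral population of diploid size
1000 splits 1667 generations ago (50 kyr at 30 yr/generation) into a
Papuan-side and an Asian-side source, each of size 1000; the admixed
population forms in a single pulse 77 generations ago (2,310 years) with
Papuan fraction 0.5137. Mutation rate 1.2e-8 and recombination rate 1.3e-8
per base per generation (8.5e-9 in the low-recombination variant modelling
the reduced crossover rate of the HLA region). Samples: 48 / 40 / 90
haploid chromosomes (24 / 20 / 45 diploid individuals) from the Papuan
source, the admixed population and the Asian source. 1500 windows make a
3 Gb genome; runs at 300+ windows give track summaries within the stated
Monte-Carlo tolerances of full scale, and the package uses such subsamples
for its fast checks. A variant with an outgroup (split at 4x the source
split) and an Asian-side sister deme (split at the pulse time) supports the
F4-ratio validation. The split-then-immediately-merge formation of the
admixed population is modelled as a single pulse — a zero-duration
split-merge is the same event.

**Array-style ascertainment.** SNP arrays are depleted of rare variants, so
simulated sites are subsampled without replacement to match a target folded
MAF histogram (50 bins of width 0.01 on (0, 0.5], pooled-sample folded MAF,
largest-remainder per-bin quotas, genome-wide target 146,090 sites for
1500 windows, scaled proportionally at reduced window counts). The default
target histogram — flat above MAF 0.05 with a linear taper below — is a
stand-in shipped as a replaceable JSON config; the genotyping array's true
spectrum is not published, and the user can supply their own histogram.
Ascertainment never alters genotypes at retained sites.

**Tract-copying admixture.** For oracle tests a fast generator draws each
haplotype's ancestry as a two-state Markov jump process along the genetic
map: switch points Poisson with rate T per Morgan, ancestry after each
switch Papuan with probability m (so Papuan tracts are exponential with
mean 1/(T(1−m)) Morgans, ~2.67 cM at T=77, m=0.5137), and alleles are
independent Bernoulli draws from the local ancestry's panel frequency.
Source panels for these tests come from a Balding–Nichols drift model.
The generator records the exact tract mosaic and true diploid dosage. It
deliberately omits drift in the admixed population and LD within ancestries
— it is an oracle for the HMM/f3/dating estimators, not a population model.

## What passing tests show — and do not show

The coalescent generator reproduces the neutral sampling distribution the
scan is calibrated against (Watterson's E[S], folded SFS shape, symmetric
source heterozygosity are all tested). It does not emulate real-data
features such as genotyping error, phasing error, variable recombination
maps within windows, or background selection, so passing tests demonstrate
correctness of the estimators under the stated model, not robustness to
array artefacts. The scan's ±3 SD flags inherit whatever bias the
local-ancestry estimator has near panel-uninformative regions.

On study conditions the simulated neutral track has mean ≈ 51–52% Papuan
and SD ≈ 12%, consistent with the drift arithmetic: binomial sampling of
40 admixed chromosomes contributes sd ≈ 7.9 points and 77 generations of
drift at Ne = 1000 contributes ≈ 9.8 points, summing in quadrature to
≈ 12.6 before posterior shrinkage.

## Numerical choices

* Dosage matrices are int8 with −1 as the missing sentinel; missing is
  never conflated with dosage 0.
* Coordinates 1-based inclusive; region length = end − start (bp); BED
  output converts to 0-based half-open.
* Call-rate filtering keeps variants with call fraction ≥ the threshold
  (PLINK `--geno` semantics).
* Merging drops strand-ambiguous A/T and C/G variants instead of guessing
  orientation from frequencies.
* PED reading counts the file-minor allele (ties broken lexicographically)
  unless an allele key is given; the PED family ID doubles as the
  population label.
* The decay fit refuses flat or non-decaying curves (fit failure) rather
  than returning a boundary estimate.
* Zero genetic distance between consecutive HMM sites means no switching,
  not an error.
* Grubbs' p uses the t-distribution bound
  `p = N P(t_{N−2} ≥ τ)`, `τ = sqrt(N(N−2)G² / ((N−1)² − N G²))`, doubled
  for the two-sided test and clipped to [0, 1]; when G is at its algebraic
  maximum the statistic is reported with p = 0.
* Stage seeds derive from the master seed through numpy `SeedSequence`
  children with fixed indices, so any stage can be rerun independently and
  all outputs are bit-reproducible for a given master seed.

## Known limitations

* The mean length of contiguous >+3 SD runs in the low-recombination null
  is an extremely noisy statistic: a full 1500-window replicate set yields
  only ~5–10 such regions, so replicate-to-replicate means range over
  hundreds of kb. A census-based check of the *true* simulated ancestry
  (tracking each admixed lineage's source population at the pulse time)
  gives the same region-length scale as the HMM track, i.e. the statistic
  is limited by the generating process and the estimator's spatial grain,
  not by inference noise. Haplotype-cluster local-ancestry estimators,
  which emit dosages in long plateaus, report systematically longer runs
  on the same data; comparisons of absolute run lengths across estimators
  should be made with that in mind.
* Two-way ancestry only; no phasing; no multi-pulse dating; no
  heterozygosity-normalized f3; sex chromosomes are out of scope.
* Grubbs' test p-values on autocorrelated tracks are anti-conservative and
  should be read as descriptive only.
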