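# Methods notes

This note records the statistical models, the numerical choices, and
the design decisions behind `hoxmir`, together with what the synthetic
data generator does and does not emulate.

## Read-level processing

The quality rule retains a read when the fraction of bases with Phred
quality ≥ 20 is ≥ 0.80, both thresholds inclusive — the semantics of
the classic FASTQ quality filter invoked as `-q 20 -p 80`. A 10 nt read
with exactly 8 such bases therefore passes.

Adapter clipping prefers the leftmost full occurrence of the 3′ adapter;
failing that, the longest adapter *prefix* of ≥ 5 nt that is a suffix of
the read (a 50 nt read whose insert is long enough truncates the
adapter, so suffix evidence must be accepted). A read with no adapter
evidence is kept unmodified rather than discarded: discarding is a
defensible alternative, but keeping is explicit, and both the overlap
and length thresholds are exposed. The minimum insert length of 15 nt
(short enough to retain anything carrying a full seed region) is
applied to every read surviving clipping, clipped or not. N bases never
match the adapter. Quality strings are truncated in step with the
sequence, and collapsing orders species by descending count then
sequence so outputs are reproducible byte for byte.

## Quantification

Alignment is exact-match on both strands with no multi-mapping limit,
via a seed-and-verify hash index (12-mer seeds, verification by
substring equality; sub-seed-length queries fall back to a direct
scan). Queries or windows containing N never match. The index is
validated in the tests against an independent naive O(nm) scan on
genomes up to 50 kb.

Assignment is deliberately asymmetric in the two read termini: the 5′
terminus must coincide exactly with the annotated 5′ terminus (start on
+, end−1 on −, 0-based), while the 3′ end is free — mature miRNA 5′ ends
are homogeneous because they define the seed, whereas 3′ ends vary by
trimming and tailing. Species longer than 27 nt are excluded as
non-mature. Overlap of ≥ 1 bp is nominally required but the 5′ anchor
implies it. Two open points are resolved as explicit, configurable
defaults: hits must lie on the annotation's strand (`require_strand`,
on), and a species satisfying the rules for two *different* mature
names credits its full count to each, while multiple loci of the *same*
name (duplicated mature genes such as miR-196a) receive a single count
(`unique_only` switches to dropping multi-name species).

## Differential expression

The model is the classic conditioned NB exact test for two-group count
data:

- Features with zero counts in every sample are removed, then a
  pseudo-count of 1 is added to every cell, so that group means are
  strictly positive and fold changes always defined.
- Size factors are median-of-ratios over features with all-positive
  counts: s_j = median_i k_ij/(∏_v k_iv)^{1/m}. These are defined only
  up to a common constant (the geometric-mean reference); tests assert
  invariance of between-sample structure, not of absolute values.
- PCA outlier rejection operates on normalized counts, samples as
  observations, features centered and unit-scaled, no log transform by
  default (a `--log`/`pca_log` option exists). Components among the
  first two with explained variance > 10% are considered; a sample
  ≥ 3 SD from the mean score is removed, once (no iteration), with size
  factors re-estimated afterwards. Zero-variance features are dropped
  with a warning.
- Dispersions: per-feature method-of-moments on the common scale,
  α̂_i = max(0, (w_i − z_i)/q̄_i²), with w_i the pooled within-condition
  variance of normalized counts, z_i = q̄_i · mean(1/s_j) the shot-noise
  term, and q̄_i the pooled mean. The trend α(μ) = a0 + a1/μ is fitted
  by a gamma-family GLM (identity link) over features with positive raw
  estimates, falling back to least squares if the GLM fails, with both
  coefficients floored at 0; essentially-Poisson data get a flat floor
  at the mean raw dispersion. The working dispersion is the
  sharing-mode maximum max(α̂_i, a0 + a1/q̄_i) — conservative by
  construction, which shows up as a type-I error below nominal in the
  calibration test band [0.02, 0.08]. Exact numerical agreement with
  any particular historical release of the reference implementation is
  not claimed.
- Exact test: pooled counts K_A, K_B are modeled as NB with means
  q̄_i·Σ_{j∈g} s_j and variances μ_g + α_i q̄_i² Σ_{j∈g} s_j². All
  probability sums run in log space with log-sum-exp; the tie rule for
  "no more probable than observed" is inclusive with a 1e-7 log-scale
  tolerance, guaranteeing p ≥ P(observed) > 0; p is clamped to [0, 1].
  The O(K) sum is capped at pooled counts of 10⁷ (an error beyond);
  NB degenerates to Poisson when the computed variance does not exceed
  the mean.
- BH step-up supports a denominator m larger than the number of
  p-values for restricted-family corrections; it is hand-written
  because standard multiple-testing helpers fix m to the list length.
- Signed fold change maps ratios below 1 to negative reciprocals, so
  |FC| ≥ 1 and down-regulation reads as, e.g., −2.19.

The regional (Hox) analysis defines a cluster as all genes whose TSS
lies in the closed interval between two boundary genes' TSSs
(strand-agnostic, boundaries included), and recomputes BH over the
cluster's p-values with a caller-chosen m. m has *no default*: the
source analyses used 55 for the Hox set but printed both 154 and 167
for the target-gene family, so the denominator is a required argument.

## Clinical models

Responses are size-factor-normalized counts rounded half-away-from-zero
to integers. The NB GLM uses a log link with variance μ + αμ², α
profiled by maximum likelihood (statsmodels' discrete NB under the
hood; AIC = 2k − 2logL counts α as a parameter). The optimizer
occasionally reports precision loss at a numerically converged point;
fits are accepted when the gradient is below 1e-3, else polished by
Nelder–Mead, else an error. Collinear designs raise a condition-number
warning. Missing covariates are handled complete-case per model, with
dropped sample ids recorded on the fit.

Backward selection drops the covariate with largest Wald p > α_stay
(default 0.05, exposed) and refits; ties break by column order. Onset
age, death age and duration are inter-dependent (duration = death −
onset in real data), so the CLI enforces at most one per model; AIC
comparison across them adjusts for CAG repeat size and reports
per-model n when complete cases differ.

## qPCR

ΔΔCT uses the control-group mean ΔCT as baseline (a multi-sample
case/control design has no single calibrator sample). The group fold
change is the mean of per-sample 2^−ΔΔCT with its SE — matching how
validation tables report "difference and standard error of fold
change" — and 2^−(mean ΔΔCT) is reported alongside since the two
differ under noise (Jensen). Replicate triples with SD > 0.5 cycles
are flagged but never dropped: no published outlier rule exists, so
exclusion would be an invention. Group tests are Welch's t on ΔCT,
two-tailed for validation designs and one-tailed (in the observed
direction) for directional replication designs.

## Synthetic data generator

The generator emulates, under one seed and bit-for-bit reproducibly:

- a toy genome with four miRNA clusters laid out like the Hox clusters,
  each bracketed by flanking boundary genes, and one mature name
  embedded at two loci (the duplicated miR-196a situation). Mature
  sequences are random 22-mers verified unique genome-wide on both
  strands (re-drawn on collision);
- NB counts at configured baselines and dispersions with planted
  case/control fold changes. Defaults plant analogues of the five
  published differentially expressed miRNAs: the miR-10b analogue at
  control mean 915.81 and fold change 28.41, the miR-1247 analogue at
  49.44 and 2.06, and three near-zero-control analogues (control means
  ≤ 1) with large fold changes. Default dispersion is 0.05, a typical
  bulk small-RNA value; remaining baselines are log-normal around 100;
- reads re-expanded one per count unit: mature genomic window,
  optionally 5′-shifted by ±1 (equal probability — the minimal
  perturbation the 5′ anchor must reject; ground-truth assignment
  becomes None) or 3′-trimmed by 1–3 nt (assignment retained), full
  adapter appended, Phred+33 qualities drawn at Q32–40. "Low-quality"
  reads are constructed to fail the 80%/Q20 rule by margin (30% of
  bases at Q ≤ 10), never by chance;
- an optional planted expression-space outlier: one control sample's
  counts scaled per-feature by exp(N(0, 2)) — a global library scaling
  alone would be absorbed by size-factor normalization, so the
  displacement must be feature-heterogeneous to be visible on PC1;
- clinical covariates from a Gaussian copula over (CAG, onset age,
  death age) with default Pearson targets +0.85 / −0.84 / −0.89,
  mapped monotonically to realistic ranges (CAG integers 40–52, onset
  25–65, death 35–80). The monotone mapping and CAG discretization
  attenuate correlations by ≲ 0.02, within the ±0.05 recovery band
  asserted at n = 2000. Duration, PMI and RIN are generated
  independently — in particular duration is *not* death − onset here,
  matching the observed (and initially surprising) lack of correlation
  of duration with the other three variables in the emulated study
  rather than the arithmetic identity;
- triplicate qPCR CT tables with CT_target = CT_ref + ΔCT_baseline −
  log2(FC) for cases plus Gaussian well noise.

What it does not emulate: sequencing substitution errors inside the
mature body (exact-match alignment would discard them by construction,
adding nothing but runtime), 5′ adapters, ligation bias, cross-mapping
between paralogous mature sequences, and library-size heterogeneity
beyond what NB sampling provides. Passing recovery tests on this
generator therefore demonstrates correctness of the *rules and
estimators*, not robustness to every artifact of real sequencing data.

## Problem sizes and determinism

Default simulated studies use 60 miRNAs in four clusters at 12 case vs
9 control — large enough for stable size factors and dispersion trends,
small enough that a full count-level analysis runs in well under a
second. The end-to-end FASTQ-level round trip in the acceptance suite
scales read depth down (baseline means near 60) since count-recovery
exactness is depth-independent; calibration checks use 1000 null
features; GLM coverage uses 100 seeds at n = 200. All randomness flows
from explicit integer seeds through per-stage `numpy` generator
streams, so every test and the acceptance script are deterministic.

## Known limitations

- The exact test's O(K) sum makes very deep features (pooled counts
  > 10⁷) an error rather than an approximation; a normal-approximation
  fallback was deliberately not added to keep the test's definition
  exact.
- The dispersion trend fit is a single pass (no outlier re-weighting);
  with < 2 usable features it degrades to a flat floor.
- The NB GLM does not regularize; quasi-separation surfaces as a
  condition-number warning, not a fix.
- `restricted_de` recomputes q-values only; p-values, means and fold
  changes pass through unchanged from the global analysis.
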