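# Methods

`tdmdscreen` re-implements, as one tested pipeline, the computational
analysis used to screen for miRNAs that are degraded through the
EBAX-1/ZSWIM8 ubiquitin-ligase pathway (target-directed miRNA degradation,
TDMD) in *C. elegans*: a null mutant of the ligase is compared to wild
type by small-RNA sequencing, and miRNAs that accumulate in the mutant are
the candidate substrates.  Every stage is exercised end-to-end on
synthetic data with planted ground truth.

## Counting model

miRNA abundance is counted by **exact 19-nt prefix matching**: a read
increments a dictionary miRNA iff the read's first 19 nt equal the miRNA's
first 19 nt.  The prefix rule deliberately pools 3'-tailed and minorly
3'-trimmed isomiRs under the parent miRNA, because 3' heterogeneity is
biology (and sequencing artefact), not identity.  Reads shorter than 19 nt
are discarded and tallied; dictionary entries with identical mature
sequences are merged under one name before counting; distinct entries
that collide only in the 19-nt prefix are a hard error (with an explicit
merge flag), since silently assigning reads to either would corrupt
counts.  piRNAs (21U-RNAs) are counted by perfect full-length matching of
the whole read to the whole reference.  Spike-in oligos are counted by the
same prefix rule but in a separate feature class and removed from the read
stream, so they never enter miRNA totals or differential expression.

Normalisation is counts-per-million of the same feature class within a
library; miRNAs get a pseudocount of 1 (numerator only — the library total
is the raw class total), piRNAs and mRNAs none.  The expression filter
keeps features whose mean wild-type CPM is ≥ 5 (inclusive; a switch
selects the strict reading).

## Differential expression

Counts are modelled per feature as negative binomial,
`var = mu + alpha * mu^2`, with median-of-ratios size factors (geometric
mean rescaled to 1) and a saturated two-group design
`log mu_ij = log s_j + beta_g(j)`.  Because the design is saturated, the
GLM maximum likelihood splits into one 1-D Newton solve per group, and the
Wald statistic uses the expected Fisher information
`I(beta_g) = sum_j mu_ij / (1 + alpha_i mu_ij)`.  `log2FC` is
`(beta_mut - beta_wt)/ln 2`, with a two-sided normal p-value; no
fold-change shrinkage is applied (raw fold changes are what the screen
reports).  Benjamini–Hochberg adjusted p-values accompany the table.

**Dispersion** is estimated per feature by method of moments on
normalised counts (pooled within-group variance), then shrunk in log
space (weight 0.5) toward a gamma-style trend `a0 + a1/mean` fitted by
least squares over the *unclipped* moment estimates.  The shrinkage is
one-sided: the raw estimate is clamped from below at the trend before
averaging.  With two replicates per group the moment estimate has two
residual degrees of freedom and falls at or below zero roughly half the
time even at substantial true dispersion, so a value below the trend
carries no usable evidence — averaging it in drives the final dispersion
orders of magnitude too low and visibly inflates null z-scores.  After
the clamp the Wald test is calibrated: on simulated global-null data
(2000 features, 2 vs 2 at 5e6 depth) the fraction of p < 0.05 sits near
0.05 and the deep tail is honest.  Estimates *above* the trend are
retained (damped), so genuinely noisy features keep wide intervals.

## BBUM sensitivity calling

Secondary, indirect consequences of losing the ligase move miRNAs in both
directions; the primary effect of interest — stabilisation of TDMD
substrates — is strictly upward.  The signed Wald p-values are therefore
modelled, split by fold-change direction, as a **bi-beta uniform
mixture**:

    positive:  f+(p) = λ + (1−λ)[θ·a_p·p^(a_p−1) + (1−θ)·a_s·p^(a_s−1)]
    negative:  f−(p) = λ + (1−λ)·a_s·p^(a_s−1)

with shared null mass λ and secondary shape `a_s` (secondary effects are
bidirectional), a primary Beta(a_p, 1) spike only on the positive side,
and `0 < a_p ≤ a_s < 1`.  The model-based FDR at p uses component tail
masses:

    FDR(p) = [λp + (1−λ)(1−θ)p^{a_s}] / [λp + (1−λ)(θp^{a_p} + (1−θ)p^{a_s})]

clipped to [0, 1]; negative-direction features are never primary and get
FDR 1.  A miRNA is called sensitive when `log2FC > 0` and FDR < 0.01
(strict).  The exact mixture parameterisation here is this package's own
concrete reconstruction of the published BBUM idea.

Numerical choices that matter:

* **Winsorisation.** p-values are clipped at 1e-10 before fitting.  Wald
  p-values underflow tens of decades below any meaningful resolution;
  left alone they make the primary spike chase the extreme tail while the
  secondary component absorbs the moderate signal, which destroys both
  the parameter estimates and sensitivity.
* **Primary-shape cap** `a_p ≤ 0.5`.  A Beta(a, 1) with `a` near 1 is
  indistinguishable from the uniform null; without the cap a degenerate
  fit (λ = 0, θ = 1, flat "primary") drives the model FDR to zero on null
  data and mass-calls false positives.  Genuine primary components sit
  far below the cap (typically a_p ≈ 0.02–0.1).
* **Optimisation.**  Maximum likelihood on logit/log-ratio transformed
  parameters, Nelder-Mead from 24 declared grid starts plus one θ ≈ 0
  start (the likelihood surface has a ridge toward a_s → 1 — a flat
  secondary — that defeats finite-difference quasi-Newton steps).  Along
  that ridge the split of null mass between λ and a flat secondary, and
  hence raw θ, is only weakly identified while the FDR curve is stable;
  candidates within 2 log-likelihood units of the optimum resolve to the
  smallest (most conservative) θ.  A two-stage mode that first fixes
  (λ, a_s) on the negative-direction features is available; joint fitting
  is the default.

On 50 simulated screens (1000 guides, 10% planted sensitive at folds 2–8,
two replicates per genotype, 5e6 reads), the caller's pooled empirical
FDR at nominal 0.01 is ≈ 0.004 and recovery of planted guides with fold
≥ 4 at baseline mean ≥ 200 is ≈ 1.0 (the acceptance script recomputes
both).

For every called guide, the **passenger-strand contrast** reports the
passenger log2FC next to the guide's; a passenger rising by more than
half (configurable) of the guide's log2FC flags a possible
transcriptional rather than degradation effect.  Loci with two
quantifiable passengers report both; passengers under the expression
cutoff are recorded as not quantifiable.

## Pool fraction degraded

Per replicate pair, wild-type raw counts are scaled so the non-sensitive
sums match the mutant (`k = Σ_mut(ns)/Σ_wt(ns)`); the surplus
`Σ_mut(s) − k·Σ_wt(s)` over the mutant's total miRNA counts estimates the
fraction of cellular miRNA molecules degraded through the ligase.
Negative surpluses are reported, not clipped — the estimator is pure
arithmetic and a negative value is a miscalibration diagnostic.  The
sensitive set is the stage-specific call set, not the development-wide
union.

## Isoform (tail/trim) profiling

Each miRNA expands into 14 exact strings: full length, 3' trims of 1–4
nt, 5' trims of 1–2 nt, and tails +A, +AA, +U, +UU, +UUU, +AU, +UA.  The
panel is configurable; this default spans the species the screen
discusses (trims up to 3 nt, mono/di-A, up to tri-U) and follows the
"most common modified species, not an exhaustive catalogue" philosophy —
reads matching no panel string (e.g. trim+tail combinations) are excluded
from the denominator.  Matching is whole-read exact; strings claimed by
more than one miRNA go to an ambiguity ledger and are excluded rather
than fractionally assigned (fractional assignment would be an unstated
model).  Fractions are per-miRNA, class count over the 14-class sum;
zero-coverage miRNAs are flagged undefined rather than NaN-propagated.

Spike-in oligos are synthesised full length, so their isoform profile
measures the apparent tailing/trimming introduced by library preparation
and sequencing.  Per-class spike rates (max across spikes) serve as the
background; genotype differences whose fractions sit below that
background in both genotypes are flagged "within error".

## Target-repression CDF analysis

Predicted targets of the stabilised miRNA family should shift left in the
distribution of mutant-vs-wild-type mRNA log2 fold changes.  Genes first
pass a wild-type expression filter of 50 raw reads (inclusive, applied to
the replicate mean; both switchable).  For each target, a control
nontarget is sampled (with replacement, seeded) among genes whose longest
annotated 3'-UTR length differs from the *target's* length by at most
15% (all predicted targets) or 10% (conserved-site targets); one control
per target by default, configurable, with realized counts logged, and
targets without eligible controls dropped and tallied.  Target and
control distributions are compared with the two-sample Kolmogorov-Smirnov
test (asymptotic, two-sided; `scipy.stats.ks_2samp`).

## piRNA block scan

piRNAs pass a support filter (≥ 1 read in every library) and the
NB Wald test; a sliding-window scan (default 100 kb window, 50 kb step)
flags windows holding ≥ 5 tested piRNAs with median log2FC ≤ −1 and
merges overlapping flagged windows into maximal intervals.  The scan uses
fold changes rather than adjusted p-values because a transcriptional
block defect shows up as coordinate sub-threshold downregulation across a
contiguous region — the signature of interest — well before individual
piRNAs reach significance.  Window, step, member and fold thresholds are
all exposed.

## Synthetic data generator

The generator emulates the study design: a dictionary of guide/passenger
mature sequences (22 nt; family members share the seed, nt 2–8), two
replicates per genotype × stage, negative-binomial counts (dispersion
0.05, log-normal library depth factors, sd 0.15), a planted sensitive
subset (default 10% of guides, folds log-uniform in [2, 8]) with
passenger folds confined to [0.9, 1.1], spike-ins at 1% of reads with
planted miscall rates of ~1e-3, a contiguous block of downregulated
piRNAs (8 adjacent piRNAs at log2FC −2), and an mRNA table with planted
target repression (−0.5 log2 for predicted, −0.8 for conserved-site
targets), log-normal 3'-UTR lengths and raw WT read counts.  A fixed seed
determines every output byte.

Two deliberate simplifications:

* The **default isoform-fraction vector** places no mass on 5'-trimmed or
  3'-trim-4 classes.  The 19-nt-prefix counter is structurally blind to
  those species — a 5' trim changes the prefix, and an 18-nt read is
  shorter than it — so the default emulates exactly the read population
  the counter can see, which keeps the emit-reads → recount round trip
  exact.  Profiling-oriented simulations pass an explicit all-14-class
  vector, which the whole-read profiler recovers in full.
* Reads are emitted already adapter-trimmed and at uniform Q40; ligation
  bias, adapter chemistry and genomic background reads are not modelled.
  Passing tests therefore validate the *computational* pipeline — they do
  not certify behaviour under adapter artefacts or alignment ambiguity,
  which the real protocol handles upstream of this package's scope.

Problem sizes used by the test suite and the acceptance script — 50
screens of 1000 guide loci for FDR/sensitivity, 2000 features for null
calibration, ~6e5 reads for isoform recovery — were chosen as the
smallest sizes at which the binomial/Poisson error bands in the
assertions are meaningfully tight.

## Known limitations

* Exactly two groups (WT vs mutant) per DE fit; multi-factor designs and
  outlier-replacement machinery are out of scope.
* The Wald test with 2 replicates per group leans on the dispersion
  trend; single-replicate designs are rejected rather than guessed at.
* BBUM assumes the null p-value distribution is uniform; a grossly
  miscalibrated upstream test will surface as an inflated fitted λ tail,
  not as an automatic correction.
* The isoform panel is exact-match only: a read with both a trim and a
  tail is excluded, so fractions are of the panel, not of all molecules.
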