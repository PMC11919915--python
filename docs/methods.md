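# Methods

This note records the models, conventions and numerical choices behind
`eegms`, and what the synthetic-cohort tests do and do not establish about
real data.

## The microstate model

The average-referenced scalp map **v**_t ∈ R^C at sample t is modeled as
**v**_t ≈ s_t · g_t · **a**_{L_t} + ε_t, where **a**_k are K unit-norm,
zero-mean template topographies, L_t the active class, g_t ≥ 0 an
amplitude, s_t ∈ {−1, +1} an irrelevant polarity, and ε_t noise.  All
comparisons between maps are therefore polarity-free: assignment uses
squared or absolute Pearson spatial correlation across channels, and a map
and its negation are the same state.

**GFP** is the spatial standard deviation per sample with the population
divisor C.  Peak picking keeps strict local maxima thinned greedily by
descending height to a minimum spacing (default 10 samples at 250 Hz),
selecting quasi-independent high-SNR snapshots.

**Modified k-means.**  Each iteration assigns every peak map to the
template maximizing the squared projection, then updates each template as
the dominant eigenvector of its cluster's outer-product sum
S_k = Σ x xᵀ; iteration stops when the relative drop of the residual
variance σ̂² (mean orthogonal residual per spatial degree of freedom,
n·(C−1)) falls below 1e−6 or at 300 iterations.  Eigenvectors are found by
power iteration warm-started from the current template.  Empty clusters
are re-seeded from the worst-fit map.  Restarts (default 100) alternate
two initializations — templates drawn from the data maps, and templates
from random surjective partitions — because coordinate ascent from
data-point starts alone can systematically miss the optimum on small
instances; the winner minimizes the cross-validation criterion

CV = σ̂² · ((C−1)/(C−1−K))²,

which penalizes K against the channel count and is undefined for
K ≥ C−1.  Ties everywhere break to the lowest class index.

**Aggregation** pools the template sets of a lower level as observations
and repeats, for `n_iter` draws, the k-means refinement started from K
sampled pooled maps, keeping the best CV.  A literal variant that only
*scores* the drawn candidate sets without refinement is available
(`refine=False`).  The hierarchy is session → subject (within stage) →
condition → global.  Canonical letters A–G are attached by solving the
assignment problem on absolute correlations against a packaged template
library; that library is a **synthetic approximation** built from
low-order position polynomials, and letters are cosmetic metadata that
never enter numerics.

**Backfitting** labels every sample by maximal absolute correlation with
no temporal smoothing, preserving raw switching dynamics.  Flat samples
get the tie-rule label with correlation 0.  GEV is
Σ(GFP_t·corr_t)² / ΣGFP_t².

## Temporal parameters

Coverage, mean duration (ms) and occurrence (/s) are computed from the
run-length encoding of a label sequence.  Truncated boundary runs count in
full, making coverage = occurrence × duration/1000 *exact*; the common
alternative of dropping boundary runs is available but breaks the
identity and is off by default.  A class that never occurs has coverage 0,
occurrence 0, and *missing* (not zero) duration — zeros would bias stage
means.  Stage summaries are unweighted means over sessions with pairwise
exclusion of missing durations.

## Statistics

The two-way fully-within ANOVA partitions sums of squares with subject as
the random blocking factor; each effect is tested against its own
factor × subject interaction.  The Greenhouse–Geisser epsilon of an effect
uses an orthonormal contrast basis (Helmert ⊗ mean) applied to the
covariance of the cell scores: ε = tr(M)²/(d·tr(M²)), clipped to
[1/d, 1].  This matches R's `car::Anova` exactly, including the
interaction epsilon (a frozen cross-check lives in the test suite).  Two
caveats the tests encode: (i) the ε estimator is biased below 1 under true
sphericity, with bias growing in effect df and shrinking in n, so
"ε ≈ 1 under compound symmetry" is asserted on a construction whose
*sample* covariance is exactly spherical; (ii) scaling degrees of freedom
by ε raises the p-value only for F ≳ 1 — for F < 1 the corrected p can be
smaller, so the conservatism property is only claimed there.  Both partial
and generalized η² are reported; neither is privileged.

Spearman correlations use average ranks with the t-approximation for p,
and a Bonferroni family of all class × dimension cells within one
parameter type (7 × 5 = 35 by default).  The observation unit is the
(subject, stage) pair — stage-mean parameters against per-stage scores —
with a per-subject mode as an option.  The t-approximation is mildly
liberal in the far tail (measured size 0.00149 at nominal 0.00143,
n = 72), which keeps the family-wise error of a 35-cell family at ≈5.1%.

## The synthetic generator

The generator emulates: K planted templates (random decorrelated maps by
default; spatially smooth dipolar/quadrupolar mixtures via
`make_smooth_topographies`); a semi-Markov label process with
gamma-distributed dwell times (shape 2 — real dwell histograms are not
exponential) whose per-class means default to 60–110 ms, a plausible
literature range that also plants a CLASS main effect; successive runs
never repeat a class, transitions default to uniform.  EEG is rendered as
sign-randomized (per run) envelope-modulated templates plus spatially
white sensor noise re-centered across channels; the default envelope is a
rectified 10 Hz sinusoid with a 10% floor, and SNR is the ratio of mean
signal GFP to noise GFP (default 4).  Evaluation scores on a continuous
1–5 scale are tied to the subject × stage mean of a chosen parameter
through a latent normal-score construction with ρ_Pearson = 2 sin(πρ/6),
so the population Spearman correlation approximates the planted target;
unplanted dimensions are pure noise.  One seed fans out to per-purpose
`SeedSequence` streams; cohorts are bit-reproducible.

**What it does not emulate.**  No volume conduction, no biophysical
sources, no artifacts (blinks, muscle), no 1/f background.  Two measured
consequences matter for interpreting test results:

* *Neighbor-correlation rule.*  Real average-referenced EEG has very high
  neighbor-channel correlations from volume conduction.  Under white
  sensor noise, a cap-shaped montage concentrates extra signal power in
  boundary channels after centering, and the sparse outer ring of the
  standard 64-channel layout (Iz/P9/P10/POz) falls below the 0.8
  threshold even on noiseless smooth data.  The false-positive audit
  therefore runs on a homogeneous full-sphere lattice with dipolar maps,
  and the pipeline driver disables the neighbor rule for random-map
  synthetic cohorts.  On real recordings the rule should be used as
  specified.
* *Duration under unsmoothed backfitting.*  At SNR 4 the envelope troughs
  relabel essentially at random, fragmenting dwell runs: estimated mean
  duration is dominated by the fragmentation rate and carries almost no
  between-subject signal (estimated-vs-true Spearman ≈ 0.07 in the demo),
  while coverage (≈ 0.73) and occurrence (≈ 0.44) survive.  This is a
  property of the no-smoothing choice, not a bug; it is why the demo
  plants its recoverable brain–behavior structure in coverage and
  occurrence.

## Problem sizes

Desk-scale defaults keep everything runnable on one CPU: the demo cohort
is 24 subjects × 9 sessions × 30 s at 250 Hz and 64 channels (the full
emulated layout of 22 sessions split 7/8/7 is the generator default for
label-level work); recovery checks use 2000 GFP-peak maps per seed and an
8-subject hierarchy; error-control Monte-Carlos run label-level only (no
EEG rendering), 300–500 replicates.  Session-level fits in the demo use 20
restarts; the default of 100 is kept wherever the CV optimum itself is
under test.

## Known limitations

* No ICA-based artifact classification: the chain exposes a pluggable
  artifact hook instead, and the epoch-probability rules carry the load.
* EDF/BDF files are read (via `mne`) but recordings are written only in
  the documented HDF5 layout; no EDF writer is bundled.
* The amplitude ±100 µV rule acts after local-channel interpolation; the
  opposite order is defensible and would reject slightly more epochs.
* The probability-based epoch rejection flags ~15–20% of perfectly clean
  epochs at its default threshold (the negative-log-density statistic is
  heavy-tailed); it localizes planted outliers exactly, which is what it
  is for.
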