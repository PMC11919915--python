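# eegms — EEG microstate dynamics and brain–behavior statistics

`eegms` is a tested pipeline for **EEG microstate analysis**: it segments
multichannel scalp EEG into a small set of quasi-stable template
topographies ("microstates"), extracts their temporal parameters, and
relates those parameters to behavioral evaluation scores.  It was built
for the setting of a longitudinal skill-training study — subjects recorded
over many short task sessions grouped into three stages, with per-stage
expert ratings on five dimensions (D1–D5) — but every component is generic.

Because raw data of that kind is rarely shareable, the package ships a
first-class **synthetic cohort generator** with planted ground truth
(template maps, semi-Markov label dynamics, sensor noise, and evaluation
scores with planted monotone associations), so the entire chain is
verifiable end to end.

## The model and the chain

At each time point the average-referenced scalp map **v**_t is modeled as
one of K unit-norm template topographies **a**_k, active with arbitrary
sign and amplitude.  The pipeline implements:

1. **Preprocessing** — zero-phase Hamming windowed-sinc band-pass (1–40 Hz),
   rule-based bad-channel detection (flatline / neighbor correlation < 0.8 /
   amplitude > 3 SD), 2-s epoching with per-epoch channel repair
   (variance, median gradient, range, deviation; |z| > 3 → spherical-spline
   interpolation), epoch rejection (±100 µV and probability criteria),
   average reference, polyphase downsampling to 250 Hz.
2. **Segmentation** — global field power GFP_t = spatial SD of **v**_t;
   GFP peaks (minimum spacing 10 samples) feed a **modified k-means**:
   assignment by maximal squared spatial correlation (polarity-free),
   template update as the dominant eigenvector of each cluster's
   outer-product sum, 100 restarts scored by the cross-validation
   criterion CV = σ̂²·((C−1)/(C−1−K))².
3. **Aggregation** — session → subject → condition → global pooling of
   template sets, each level re-clustered 100 times from sampled
   candidates and scored by CV; canonical letters A–G attached by optimal
   assignment against a template library.
4. **Backfitting** — every sample labeled with argmax_k |corr(**v**_t, **a**_k)|,
   deliberately with *no temporal smoothing*; GEV reports the
   GFP-weighted explained variance.
5. **Parameters** — per class: coverage (fraction of time), mean duration
   (ms per visit), occurrence (visits/s); the identity
   coverage = occurrence × duration/1000 holds exactly.
6. **Statistics** — 7×3 and 5×3 fully-within-subject ANOVA with
   Greenhouse–Geisser correction and η² (partial and generalized),
   Bonferroni paired t-tests, and Bonferroni-corrected Spearman
   correlations between parameters (per class) and evaluation dimensions.

## Worked example

`configs/demo.yaml` defines a desk-scale cohort — 24 subjects, 64
channels, 7 classes, 9 × 30 s sessions over three stages, SNR 4 — with
three planted brain–behavior effects.  The numbered drivers run the whole
study:

```
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_checks.py
python analysis/03_run_pipeline.py
python analysis/04_parameter_recovery.py
python analysis/05_statistics_report.py
```

Output of `03`/`04`/`05` (abridged):

```
global fit: CV=6.1373e-05, peak-map GEV=0.997, mean backfit GEV=0.811
mean estimated-vs-true Spearman rho per parameter:
coverage      0.732
duration      0.069
occurrence    0.444
map recovery mean |corr|: 0.965
coverage: CLASS F(6,138)=202.19, p_GG=2.6e-45, eta2_g=0.754 | STAGE F=6.90, p_GG=0.02
Bonferroni-significant correlation cells (2/105):
  coverage   class F x D1: rho=+0.37 (p_bonf=0.0427)
  coverage   class G x D5: rho=-0.39 (p_bonf=0.026)
```

Reading: the seven planted maps are recovered almost perfectly
(mean |corr| 0.965) and backfitting explains 81% of the GFP-weighted
variance.  The per-class dwell means planted in the generator surface as a
large CLASS main effect on coverage and occurrence.  Of the planted
correlations, the positive coverage→D1 effect is recovered at the
Bonferroni threshold, and the planted negative occurrence effect surfaces
through the tightly coupled coverage of the same class (negative, D5);
duration carries almost no signal — an expected cost of *unsmoothed*
backfitting under noise (see `docs/methods.md`).

A `eegms` command-line tool exposes the same stages
(`simulate`, `preprocess`, `fit`, `aggregate`, `backfit`, `params`,
`stats`, `run`); try `eegms run --config configs/demo.yaml`.

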