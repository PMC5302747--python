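# Methods

This note documents the models, parameter choices and numerical
conventions behind `radmarkers`, and what the synthetic-data experiments
do and do not establish about real serum-proteome data.

## Study design being emulated

Mice receive a single localized skin dose of 0, 20, 40 or 80 Gy; serum
is collected on day 3 or day 7 post-irradiation, during the clinical
latency phase; animals come from two independent experimental series
(batches).  The gel platform quantifies 941 spot features on 16 animals
per dose and day; the MS platform profiles 32 animals per dose and day
and yields on the order of 100–130 peak clusters.  Seven group
comparisons are analyzed: sham vs irradiated on day 3, day 7 and both
days pooled (triage), and the severity contrasts 20 vs 40+80 Gy and
20+40 vs 80 Gy on each day (prognosis; the 40 Gy group is transitional
and is pooled with one of its neighbors).

## Simulation model

**Gel-spot matrices.**  Log-intensities are
`mu_f + batch(b,f) + marker(g,f) + eps`, with per-feature baselines
`mu_f ~ N(baseline_log_mean, baseline_log_sd²)`, per-(batch, feature)
nuisance `N(0, batch_sd²)`, and residual `N(0, residual_sd²)`; values
are exposed as `exp(·)` on the linear scale, matching the universally
log-normal behavior of spot volumes.  Defaults: `baseline_log_sd` 0.5
(spot-to-spot abundance spread), `batch_sd` 0.1 (series-level nuisance;
dye effects are folded in here because a dye-swap design cancels them in
expectation), `residual_sd` 0.3 (combined biological + technical CV of
roughly 30 %, typical of serum 2-D gels).  Planted markers multiply
group means: `exposure` markers by a single ratio for every irradiated
group, `dose_monotone` markers by `ratio^level` with level = dose rank.
The default planted panel has 15 features whose effect structure mirrors
acute-phase serum responses: mostly ±1.1–2.0-fold exposure and dose
trends, one large 7.1-fold up-regulation with a 2.5-fold dose trend,
opposite-direction pairs included.  Dose trends are planted per level as
the square root of the end-to-end fold, since the extreme irradiated
groups sit two levels apart.

**SELDI spectra.**  Each spectrum is a sum of Gaussian peaks (width
`peak_width_frac · m/z`; default 0.2 % of mass) at per-spectrum jittered
positions (`uniform(±mass_jitter_frac)`, default 0.1 %, multiplicative to
match the relative cluster window), a smooth exponentially decaying
baseline, and white noise.  Peak amplitudes are log-normal with a stated
CV; a per-peak `presence` fraction allows peaks absent from part of the
cohort.  QC-pool spectra carry every peak at its population mean with
only technical noise (`qc_cv`, default 0.15, the middle of the 10–20 %
reproducibility band such pools show in practice); 16 QC replicates by
default, one per chip array of eight spots in a 128-sample experiment.
The latent per-sample amplitude matrix is returned for oracle tests.

**What the generator does not model:** gel images and spot detection,
spot trains / post-translational microheterogeneity, isotopes and
adducts, instrument warping, heavy-tailed inter-individual outliers.
Passing tests on these simulations show the *statistical machinery* is
correct and calibrated; they cannot show that real serum data satisfy
the log-normal or independent-feature assumptions.

## Preprocessing conventions (SELDI)

The vendor software's algorithms are undisclosed, so documented
stand-ins are used: baseline = rolling minimum then moving average over
a window in Daltons (default 250 Da, wide against any peak), clipped at
zero; noise = 1.4826·MAD of first differences / √2 (robust to sparse
peaks); detection = local maxima of a 5-point-smoothed trace after
removing a 201-point rolling-median floor (this guards against the
~2.5σ offset a lower-envelope baseline leaves behind), requiring both
height above the floor and prominence ≥ S/N-threshold × noise.  The
thresholds "2.5" and "3.0" are S/N ratios (the percent signs in the
original description are typographical; a threshold of 2.5 *percent*
would detect everything).  Clustering is single linkage over pooled peak
masses with chaining inside 0.3 % of mass; a cluster is *first-pass* if
its S/N ≥ 2.5 members appear in ≥ 50 % of spectra, otherwise it is kept
as *completion* if its S/N ≥ 3.0 members appear in ≥ 10 %.  Because the
completion S/N is the stricter of the two at the defaults, the passes
partition one clustering and every detected peak belongs to at most one
cluster.  Representative masses are intensity-weighted member means;
missing cells are read from the sample's processed spectrum at the
cluster mass (or 0 without spectra).  QC CVs use the ddof = 1 sd
convention.

A density caveat: at 0.2 % peak widths and ~1.3 % log-spacing,
neighboring low-mass peaks become flank-contiguous and no windowed
noise-floor estimate is reliable; scenario configurations that need
exact latent-truth recovery use 0.1 % widths (a realistic instrument
resolution) so inter-peak gaps exist.

## Statistics

Tests run on natural-log intensities; fold changes are reported on the
linear scale with the signed convention (+r / −1/r; "=" at 1.0).  The
permutation test statistic is the absolute difference of group means,
labels permuted jointly across features (B = 9999 by default), giving
p = (b+1)/(B+1); an optional batch-stratified scheme permutes within
series.  BY adjustment uses the standard step-up implementation and is
applied over all features of a comparison, not only selected ones.
Candidate screening uses unadjusted ANOVA p < 0.05, as in the emulated
workflow.

ANOVA degeneracies (zero variance, equal means) yield p = 1 plus a
flag.  A permutation p can never fall below 1/(B+1); with m = 941
features the smallest BY step-up threshold is 0.05/(m·c(m)) ≈ 4·10⁻⁵·k,
so B must be large for BY-on-permutation-p to have any power — the FDR
simulation uses effects strong enough to reach the floor.

## Stability selection

PLS-DA importance is VIP (the convention of the R modeling ecosystems
when PLS importance is requested); the PLS fit centers and unit-scales
X, codes classes ±1, and uses 2 components by default (not stated in
the emulated workflow; exposed in config).  Splits are stratified to
avoid empty-class learning sets at n = 16 per group.  RF importance is
Gini mean-decrease (permutation importance available); the retention
count (default 24 of 30) is a free parameter the emulated workflow never
states.  All randomness derives from a master seed through named
substreams (stage index → repeat index → 31-bit child seed).

A property worth knowing: because the 10 PLS-DA repeats are 70 %
subsamples of *one* dataset, their top-VIP lists are strongly
correlated.  On pure-null data the "good" set (frequency ≥ 8/10) is
therefore *usually non-empty* (typically 1–4 features) — stability
selection on a single dataset does not self-calibrate, and its output
must be read together with a null or permutation reference.  The
acceptance suite measures exactly this.

## Panel evaluation

Stepwise LDA defaults to the classic Wilks'-lambda rule (F-to-enter
3.84, F-to-remove 2.71, ties to the smaller index) — the criterion the
stepwise-DA software behind the emulated workflow implements.  A
CV-accuracy forward criterion (tolerance 1/(2n)) is available but is
documented as prone to truncating panels: with a 1:3 class imbalance,
accuracy saturates at the majority rate and stops admitting variables
that still improve the ROC.  Stepwise logistic regression searches
bidirectionally from the intercept-only model, minimizing AIC; perfect
separation falls back to a ridge-penalized fit, flagged.  ROC scores are
the LDA discriminant value or the logistic linear predictor; AUC is
trapezoidal and equals tie-half-credited pair concordance.  Because it
is generally ambiguous whether a reported AUC is resubstitution,
cross-validated or held-out, the evaluation report emits all three,
labeled.  PCA runs on centered, unit-scaled panel variables with signs
fixed by the largest loading.

Two evaluation protocols exist and differ materially at n = 64:

* `selection_scope='train'` (pipeline default): stability selection sees
  only the 70 % learning split; held-out metrics are unbiased, but
  selection loses power.
* `selection_scope='all'` (the emulated workflow's protocol, used by the
  acceptance script): selection sees every sample of the comparison and
  only the stepwise refit/scoring is split; held-out AUCs are
  optimistically biased under the null (measured mean ≈ 0.66 on
  label-permuted data vs 0.48 for the nested protocol).

## Problem sizes in tests

The test suite runs the study-scale designs (941 features, 4 × 16
samples) wherever the measured property depends on them; resampling
depths are scaled where they do not: the Random-Forest recovery
experiment uses 200 trees × 10 iterations with retention 8/10 (the same
80 % ratio as the full 1000 × 30 design), the null-band experiment uses
25 seeds, and the FDR simulation uses 200 features × 200 replicates at
B = 1999.

## Known limitations

* Selection frequencies, not p-values: neither selector yields an error
  rate; calibration must come from the permutation/null machinery.
* The RF retention step is sensitive to between-dataset variation in
  realized effect sizes; marker recovery rates quoted for one planted
  effect size do not transfer to weaker effects.
* LDA assumes equal class covariances; heavy imbalance additionally
  shifts its accuracy-optimal threshold away from the AUC-relevant
  ordering.
* No mixed models, no dye-effect modeling, no protein identification;
  spot trains are treated as independent features.
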