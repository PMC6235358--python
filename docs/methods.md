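# Methods

`vtwarn` implements an early-warning pipeline for ventricular
tachyarrhythmia: given the R-R interval buffer an implantable
cardioverter-defibrillator (ICD) records (up to 2048 annotated intervals),
it extracts heart-rate-variability (HRV) features and classifies the buffer
as a regular rhythm or a rhythm that immediately precedes an appropriate
shock. Two configurations are supported: a *five-minute* warning (the last
5 minutes before the event are trimmed off, 1000-interval analysis windows)
and a *ten-second* warning (10 s trimmed, 1600-interval windows).

Because the original trial data are not publicly deposited, the package
ships a synthetic cohort generator calibrated to the published group
statistics; every end-to-end number the test suite or the acceptance script
reports is computed on such cohorts.

## Record cleaning and windowing

Beats are annotated `N` (normal), `V` (premature ventricular) or `P`
(compensatory pause). Cleaning applies two rules in one ordered pass:

1. beats labeled `V`/`P` are removed;
2. an `N` interval deviating more than 20% from the running median of the
   previous 5 accepted intervals is removed together with the immediately
   following beat (treated as its compensatory pause). The rule arms after
   5 accepted beats.

The label rule implements the explicit annotations; the timing rule is a
standard HRV cleaning heuristic for unlabeled ectopy. The exact exclusion
criterion used in the original processing is not documented; this pair of
rules was chosen because it is deterministic, idempotent and removes an
injected PVC/pause pair exactly.

Records keep only if ≥ 1700 normal beats survive cleaning. Window
extraction drops every interval whose cumulative end-time lies within the
warning horizon (300 s or 10 s) of the final beat time and returns the last
*m* surviving intervals (1000 or 1600). Regular records have no event, but
the identical trim is applied relative to the record end so the two classes
pass through the same transformation and the classifier cannot key on a
preprocessing artifact. Cumulative times are interval end-times; the first
interval ends at t = its own duration (a device buffer has no absolute
onset).

## Scalar features

All features are computed on the analysis window, with population (1/N)
variances throughout:

* **mean N-N** — arithmetic mean interval (s).
* **Hjorth mobility / complexity** — `sqrt(var(Δy)/var(y))` and
  `mobility(Δy)/mobility(y)`, with Δ the first difference over *beat index*
  (dimensionless, matching the magnitudes of the reference tables).
* **DFA α₁ / α₂** — the series is mean-centered and integrated; for every
  integer box size n the profile is split into non-overlapping boxes,
  linearly detrended per box, and F(n) is the RMS residual. α₁ is the OLS
  slope of log F vs log n over n ∈ [4, 16], α₂ over n ∈ [16, 64] — the
  standard short/long-range convention; the original's "fastdfa" routine is
  an optimization of the same estimator, not a different statistic.
* **Five log-spaced band powers** — the classical Lomb periodogram on the
  uneven time axis (cumulative interval sums). "0 Hz" cannot anchor a
  logarithmic scale, so the five bins span [1/T, 0.5 Hz] with edges
  equispaced in log₁₀, where T is the window duration: the lowest resolvable
  frequency is the only deterministic, window-adaptive choice. The
  evaluation grid is oversampled 4× (spacing 1/(4T)); band power is the
  rectangle-rule sum of periodogram density × Δf, so the five bins sum
  exactly to the total grid power. The raw Lomb ordinate is rescaled by
  twice the mean sampling interval, which makes the summed density estimate
  the series variance (s²) and equals the DFT periodogram scaling on an
  even grid. The Lomb kernel evaluates the classical ordinates on the
  uniform grid with per-sample trig recurrences (numba-compiled); tests pin
  it to the DFT periodogram at 10⁻⁶ and to scipy's direct evaluation.

## Tachogram PCA and rank selection

Training windows form the columns of an m × n matrix. The mean column
profile is subtracted from every column ("the mean of all columns" is read
as the average *column vector*: per-column means would reduce the transform
to a plain z-score and destroy the cross-record centering that gives the
first PC its heart-rate-trend interpretation); each column is then divided
by its own standard deviation. The reduced SVD R = U S Vᵀ follows, and the
retained rank k counts singular values above the optimal hard threshold
τ\* = ω(β)·median(singular values), with the cubic approximation
ω(β) = 0.56β³ − 0.95β² + 1.82β + 1.43 for unknown noise level (β = n/m).
k is floored at 1. Each principal component's sign is fixed by orienting it
so its projection onto an increasing beat-index ramp is positive — so a
positive first-PC coefficient always means the N-N interval lengthens over
the window.

Out-of-sample records are standardized with the *training* mean profile and
their *own* standard deviation (mirroring the per-column training rule —
the original work does not state its projection rule, so this one is
declared, not inferred) and projected onto the first k components.

On calibrated synthetic cohorts the threshold typically retains k ≈ 150–190
components rather than the ~18 reported on the real data. This is an honest
property of the generator: its records are random-phase processes whose
shared second moment is a smooth power-law spectrum, so the singular-value
spectrum decays smoothly over the ~150 modes that carry the power law and
the median-calibrated threshold keeps most of them. A generator that
reproduced k ≈ 18 would need nearly all cross-record structure confined to
~18 modes above a strong white floor — which would put the floor above the
power law at DFA box scales and destroy the α₂ calibration. Matching the
DFA targets was prioritized; the hard threshold's correctness itself is
verified independently on planted-rank matrices, where it recovers the
planted rank exactly.

## Classification protocol

Per trial: (1) the regular class is undersampled without replacement to the
pre-shock count; (2) a stratified 80/20 record-level split
(round(0.8 × class size) per class — 230 + 230 balanced records give the
184 + 184 training layout); (3) the PCA is fit on training windows only and
every balanced record is projected; (4) predictors are assembled in the
order PC 1..k, α₁, α₂, mean N-N, band powers 1–5, Hjorth complexity,
Hjorth mobility; (5) classifiers are trained and the held-out rows scored.
The default protocol repeats this 100 times; trial i derives all its
randomness from `seed + i`, so any single trial is reproducible in
isolation.

* **Random forest** — 500 trees, bootstrap aggregation, √p features per
  candidate split, unlimited depth (scikit-learn defaults of the cited
  algorithm; the original's settings are unstated). Score = fraction of
  trees voting pre-shock; decision threshold 0.5. Predictor importance is
  Breiman's out-of-bag permutation importance: per tree, the increase in
  misclassification on its out-of-bag rows when one predictor is permuted,
  averaged over trees. The per-tree bootstrap indices are reconstructed
  from each tree's random state and verified against the forest's own OOB
  score in a test.
* **Linear SVM** — features z-scored with training statistics only, linear
  kernel, C = 1.0 (unstated in the original; the standard default). Score =
  signed decision margin.

Sensitivity = TP/(TP+FN) with pre-shock positive; specificity = TN/(TN+FP);
AUC is computed by the rank (Mann–Whitney) identity with midranks.
Aggregates are reported as mean (SD) over trials. Records from one patient
may appear in both splits, matching the study's apparent record-level
protocol; `group_by_patient=True` provides the leakage-safe alternative in
which patients never straddle the split.

Group statistics (median, IQR, two-sided Mann–Whitney U) are computed on
the full unbalanced cohort. The U-test uses exact enumeration for
min(n) ≤ 8 (without ties) and the tie-corrected normal approximation with
continuity correction otherwise; the approximation agrees with exact
enumeration to ~10% for mid-range p but is unreliable for p below ~0.01 at
such sample sizes.

## Synthetic cohort generator

Each record is a beat-indexed process

    RR_i = μ + s·(i − (n−1)/2) + f_i,   clipped to [0.3, 2.0] s, 1 ms grid,

with per-record draws: μ log-normal matched to the published median and IQR
of the per-record mean N-N interval; slope s normal (regular: small
positive lengthening; pre-shock: negative — heart-rate acceleration before
the arrhythmia, the feature the first PC picks up); and fluctuation f from
frequency-domain synthesis with amplitude ∝ f^(−γ/2) in cycles/beat,
random phases, a steep roll-off above a spectral knee, plus a
high-frequency (> 0.15 cycles/beat) component carrying `hf_fraction` of the
variance. The trend is centered on the record midpoint so μ remains the
record mean and the mean-N-N calibration is unbiased by the slope draw.

γ is tied to the published long-range DFA exponents by the standard
fractional-Gaussian-noise relation α = (γ+1)/2 (regular: α₂ = 1.03 → γ =
1.06; pre-shock: α₂ = 0.644 → γ = 0.29). The knee, `hf_fraction` and the
dispersion constants were tuned once with `scripts/calibrate_synth.py` and
frozen in `default_class_specs`. Per-record dispersions (on γ, the knee,
the HF fraction and the fluctuation SD) spread the within-class marginals
toward the published IQRs; without them each class would collapse onto one
spectrum and the classifier would separate the classes almost perfectly,
which the published moderate accuracies rule out. The pre-shock trend SDs
were sized so that the first-PC coefficient distributions overlap roughly
like the published coefficient quartiles. The fluctuation SD scales
proportionally with μ (HRV magnitude grows with the mean interval), which
also keeps the 20%-of-median timing filter's removal rate roughly
independent of heart rate. Ectopy is injected as non-overlapping PVC/pause
pairs (0.6×, 1.4× the local interval — duration-conserving), at 1%/2% per
beat for the regular/pre-shock class. Per-record draws of μ and the slope
are truncated to physiological bounds (μ ∈ [0.35, 1.8] s,
|slope| ≤ 1.5·10⁻⁴ s/beat); the cuts sit more than 3σ from the calibrated
medians, so the matched marginals are unaffected while extreme tail draws
cannot push a whole record into the interval clipping floor.

Patients receive Poisson-distributed regular-record counts (mean 8.5,
conditioned ≥ 1); pre-shock records attach to patients drawn from the same
pool and are event-anchored. Records are emitted at 1 ms resolution, so a
cohort round-trips losslessly through the plain-text record format.

**What the generator does and does not emulate.** It reproduces: the class
sizes and imbalance, the records-per-patient structure, the mean-N-N
medians and IQRs, the direction of every published cross-class median
difference (all ten features, both horizons), the DFA-exponent targets
under pure power-law synthesis, and an exclusion stage that discards a
realistic fraction of records. It does *not* reproduce the absolute
magnitudes of Hjorth complexity, α₁, or the band powers: the published
values of mobility (~0.08), complexity (~1.7), α₁ (~0.66) and the printed
band powers are not jointly attainable by any single stationary
beat-indexed process — a spectrum thin enough above 0.05 cycles/beat to
give mobility 0.08 cannot simultaneously put the printed fraction of power
in the top frequency bins or hold complexity near 1.7. The calibration
therefore prioritizes (in order): mean N-N, the DFA recovery targets, and
the cross-class orderings; mobility lands near its printed scale, while
complexity and α₁ are high by a factor of ~3 with the printed *orderings*
preserved. Passing tests consequently demonstrate protocol and estimator
correctness and directional fidelity, not that real ICD data would yield
these exact feature values.

Classification accuracy is emergent, not tuned: with the default class
specifications the repeated-trial mean random-forest AUC lands in the
0.90–0.97 range on both horizons, above the published 0.81/0.88 — the
synthetic classes are somewhat easier to separate than the real ones — and
the ten-second configuration scores consistently higher than the
five-minute one, reproducing the published ordering (longer windows give
tighter feature estimates, and the ten-second window sits closer to the
pre-shock heart-rate acceleration).

## Numerical choices and degenerate inputs

* Population (1/N) variance everywhere; OLS slopes by `numpy.polyfit`.
* The horizon trim uses a 10⁻⁹ s tolerance at the cutoff so cumulative-sum
  rounding cannot flip a boundary interval.
* Zero-variance windows or columns raise typed errors naming the record; a
  column whose centering residue is below 10⁻¹⁰ of the matrix magnitude is
  treated as zero-variance.
* SVD non-convergence surfaces as `LinAlgError`; it is never masked.
* Evaluation trials that fail are skipped and counted; more than 10%
  failures aborts the whole run.
* Problem sizes: the acceptance script uses the documented 500 + 500-record
  cohorts with 100 trials; the test suite runs the same machinery on a
  250 + 250 cohort with 30 trials and fewer Monte-Carlo replicates, chosen
  as the smallest sizes at which the stochastic assertions have comfortable
  margins.

## Known limitations

* The generator is statistical, not mechanistic — no sinus-node/IPFM model,
  no atrial fibrillation or AV-block rhythms, no within-patient correlation
  (a per-patient random-effect knob exists but defaults to off, since the
  original reports no within-patient structure to calibrate to).
* The Gavish–Donoho retained rank on synthetic cohorts (~150–190) differs
  from the ~18 reported on real data; see the PCA section.
* Feature-magnitude mismatches for complexity, α₁ and band powers are
  documented above and flagged by `calibration_report`.
* The record-level split can place records of one patient in both train and
  test sets; this mirrors the study protocol but inflates accuracy relative
  to the patient-grouped alternative.
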