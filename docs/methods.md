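# Methods

`datscreen` models a clinical screening task in Parkinson's disease (PD):
deciding from objective wearable-sensor data whether a person's motor
fluctuations have reached the point where device-assisted therapies (DAT —
deep brain stimulation or pump-delivered infusions) should be considered.
The input is the output of a wrist-worn logger that emits a bradykinesia
score (BKS) and a dyskinesia score (DKS) every two minutes over a
multi-day recording (6 days = 4320 epochs), plus tremor/worn flags and the
programmed medication-reminder schedule. The reference standard is the
specialist's judgment that a subject does (CP) or does not (CN) meet the
motor criteria for DAT.

## Feature extraction

All summary statistics except PTI and PTT are computed over *valid*
epochs: recorded between 09:00 and 18:00 (half-open window), device worn,
no artifact flag, and BKS ≤ 80 (immobility exclusion). Percentiles use
the linear-interpolation convention.

- **median BKS / BKS-25 / BKS-75, median DKS / DKS-75** — daytime
  percentiles over valid epochs. The BKS interquartile spread is the
  signature of fluctuation.
- **PTB (percent time bradykinetic, "off")** — candidate epochs have BKS
  in [26.1, 49.4], or BKS > 49.9 with tremor present (tremor corrupts the
  bradykinesia score upward). A recording-level eligibility gate requires
  the 25th BKS percentile > 18.5 and the 90th < 80; a recording failing
  the gate has no measurable off time and scores PTB = 0 with an explicit
  `gate_failed` flag (well-treated or immobility-dominated recordings).
  Candidates are smoothed by a centered 30-minute (15-epoch)
  moving-majority filter: an epoch is "off" iff strictly more than half of
  the valid epochs in its window are candidates. Windows shrink at
  recording edges and across not-worn gaps instead of padding — no data
  are fabricated at boundaries.
- **PTD (percent time dyskinetic)** — valid epochs with DKS > 7, smoothed
  by the same majority filter (window length configurable, default 30
  minutes to mirror PTB).
- **PTI / PTT** — percent of *worn daytime* epochs with BKS > 80
  (daytime-sleep proxy) / containing tremor. Immobile epochs stay in
  these denominators.
- **doses/day** — programmed reminders per recording day.
  Acknowledgement flags are retained in the schedule type but do not
  enter the rate.

The gate percentiles are computed after the immobility exclusion (the
choice is visible only for recordings with substantial immobile time).

## Feature ranking (JMIM)

Continuous features are discretized into equal-frequency bins (default 4
— with ~112 training rows this keeps expected marginal bin counts near
28); dose counts are coded by their distinct values. Mutual information
uses the plug-in estimator in bits. Ranking is greedy joint-mutual-
information maximization: the first feature maximizes marginal I(X;Y);
each subsequent pick maximizes `min over selected s of I((X_f, X_s); Y)` —
a max-min criterion rewarding relevance while penalizing redundancy.
Ties break by input column order. No stopping rule is applied by default
(all eight candidate features are retained by the screening model); a
minimum-criterion threshold is available in the API.

## Classifiers and the 0–100 score

Both models consume eight features — doses/day, DKS-75, BKS-25, BKS-75,
PTD, PTI, PTT, PTB — z-scored with statistics estimated on the
construction rows only.

- **Linear**: L2-penalized logistic regression;
  score = 100·σ(w·z + b).
- **Nonlinear**: bagging over B = 100 Gaussian-RBF support-vector
  classifiers. Each base is fit on a size-n bootstrap resample (redrawn
  if single-class); its decision values are mapped to probabilities by a
  Platt-style sigmoid fit on the base's out-of-bag rows (fallback: all
  construction rows when the out-of-bag rows are single-class). The
  ensemble score is 100 × the mean base probability; a hard label (CP iff
  score ≥ 50) coincides with the majority vote of the calibrated bases
  except exactly at ties. A pure vote cannot give the required
  continuous score, hence the mean-probability aggregation.

Hyperparameters (C ∈ {0.1, 1, 10}, γ ∈ {0.01, 0.1, 1} on standardized
features) are tuned by stratified 5-fold cross-validation maximizing mean
out-of-fold ROC AUC. Grid evaluation uses a single un-bagged base per
fold: its decision values are a monotone transform of the calibrated
ensemble score in expectation, so fold AUC is unchanged and tuning stays
~100× cheaper. Ties prefer stronger regularization (smaller C), then
smaller γ.

Scores carry risk bands: low (< 20), intermediate (20–60), high (≥ 60).

### Operating threshold

The referral threshold is the Youden optimum (maximizing sensitivity +
specificity − 1; ties resolved toward the higher threshold — fewer
referrals) chosen on the construction set and frozen for the test set.
For the bagged model the construction-set scores used for threshold
selection are **out-of-bag scores** (each row scored only by bases whose
resample missed it): resubstitution scores of a bagged ensemble are
near-separated, which pushes the threshold to the top of the score gap
and collapses out-of-sample sensitivity.

## Response assessment

After a therapeutic intervention (oral-therapy optimization or DBS), a
successful optimization is expected to drop the score by roughly
(pre − 20). `classify_response(pre, post, tolerance=15)` labels a pair:

- `low_risk_stable` — both scores below 60 and essentially unchanged;
- `predicted_response` — observed drop within ±tolerance of (pre − 20);
- `unmasked_need` — the score *rose* beyond tolerance into the high band
  (treating under-medication revealed fluctuations/dyskinesia);
- `failed_optimization` — otherwise (score stayed high; DAT indicated).

The 15-point default tolerance is a stated approximation of a response
band whose exact published geometry is figure-only; it is configurable.

## Synthetic cohorts

Feature-space cohorts are drawn from a Gaussian copula over per-group
two-parameter marginals quantile-matched to the published CP/CN group
medians and interquartile ranges: percent-of-time features are
logit-normal, score medians and spreads log-normal, doses/day a rounded
normal. Continuous fits anchor the location at the transformed median
and take the scale from the transformed IQR; since several published
triples are asymmetric in the transformed space, a two-parameter family
reproduces the median exactly and the IQR width, not all three quantiles
(the group medians are what the calibration contrasts depend on). The
count family instead uses the least-squares location over the three
transformed quantiles, which reproduces integer quartile triples such as
(5, 5–6) exactly after rounding.

Quantities not published at group level are stated assumptions: the
within-recording BKS-IQR width (CP wider — fluctuation is the CP
hallmark) and DKS-75 distributions, the CP PTI upper quartile (6.8; the
source prints a garbled value), the CONTROL group (near-floor percent
features, no levodopa), and the rank-correlation structure (PTD–DKS75
0.7, PTB–median-BKS 0.6, 0.2 elsewhere; converted to latent Pearson
correlations and repaired to the nearest unit-diagonal PSD matrix).
Because PTT is published as identical across groups, it is nearly
uninformative in the generator — by design.

What a green surrogate test establishes: that the *pipeline* (split,
tuning, training, calibration, thresholding, ROC) recovers the separation
implied by the published group distributions. It does not validate the
clinical claim itself, which depends on unavailable patient data; nor
does the generator model artifacts (exercise-inflated DKS, missed lower
limb dyskinesia), clinician inconsistency, or longitudinal drift.

## Synthetic epoch recordings

Each levodopa dose at time t₀ contributes an effect
E(u) = (u/tp)·exp(1 − u/tp), u = t − t₀ ∈ [0, duration], a unimodal
curve peaking at u = tp. Then

    BKS(t) = clip(baseline − amplitude·ΣE + noise, 0, 160)
    DKS(t) = max(0, gain·max(0, ΣE − threshold) + noise)

Night epochs (00:00–06:00) follow a sleep regime of high noisy BKS.
Defaults: 6 days, doses at 08:00/10:30/13:00/15:30, baseline 30,
amplitude 9.5, tp 1 h, duration 2 h, BKS noise sd 2, DKS gain 40 /
threshold 0.7 / noise sd 1, tremor probability 0.01 per epoch.

The baseline/amplitude/noise geometry is constrained by the scoring rules
themselves: the PTB gate (BKS-25 > 18.5) and the off band lower edge
(26.1) leave a 7.6-point corridor for the medicated plateau, so the
plateau is placed at 20.5 (≈2.8 noise sd below the band edge) and the
unmedicated state mid-band at 30. With a wider noise sd the programmed
off-fraction would be ill-defined — state membership itself becomes
ambiguous — which is a property of the scoring bands, not of the
extractor. Ground truth records the noise-free fraction of daytime worn
epochs inside the off band and above the dyskinesia threshold;
`phenotype_for_off_fraction` solves for the effect duration reaching a
requested off-fraction by monotone root search on the noise-free
trajectory (feasible range ≈ 0.13–0.93 under default dosing).

## Surrogate experiment

One replicate r (seed + r): sample 172 subjects (86 CP / 86 CN), split
112/60 class-stratified with a per-feature Mann–Whitney similarity check
between matched classes (redraw with incremented seed while any
p ≤ 0.05, up to 100 times), tune by 5-fold CV, train the bagged
nonlinear classifier, pick the Youden threshold on out-of-bag
construction scores, and evaluate AUC/sensitivity/specificity on the
held-out 60. The default report aggregates 25 replicates by the median.
With seeds 1–25 the default calibration yields median test AUC ≈ 0.96
and specificity ≈ 93%; median sensitivity lands at 86.7% — note that with
30 CP test subjects sensitivity is quantized in steps of 3.33%.

## Numerical notes

- Percentile and equal-frequency-bin edges use linear interpolation;
  discretization ties share a code.
- The moving-majority filter demands *strictly* more than half; windows
  truncate at edges.
- "Majority" ties in Youden's J break toward the higher threshold; the
  sweep's sentinel top threshold is reported as (max score + 1) if ever
  selected.
- Zero-variance features standardize with scale 1 and a warning.
- All stochastic steps consume explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence.spawn`; repeated runs are
  bit-identical, and models serialize to JSON that round-trips scores
  exactly.
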