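# Methods

`pttrack` tests whether pulse transit time measured from the ECG R-wave to
the arterial systolic peak (PTT-RA) tracks systolic blood pressure (SBP)
during rapid hypotensive episodes. This note documents the analysis model,
the synthetic-data generator that stands in for raw ICU recordings, the
numerical choices, and what the bundled checks do and do not demonstrate.

## The analysis model

Pulse-wave velocity rises with transmural pressure, so transit time should
fall as pressure rises; within a subject the relationship over a short
episode is treated as linear:

    SBP_AV = alpha1 * PTT-RA_AV + beta1          (primary model)
    SBP_AV = alpha2 * HR_AV     + beta2          (negative control)

where the `_AV` series are Savitzky-Golay moving averages (order 1, width 21
beats: a straight line fitted through the 10 preceding and 10 following
heartbeats, evaluated at the center beat). Averaging targets short-term
trends rather than beat-to-beat fluctuation, and suppresses both the
respiration-driven oscillations of HR and BP (which occur with a phase
offset and would otherwise distort the beat-level relationship) and the
coarse temporal quantization of PTT at monitor sample rates. Heart rate is
regressed identically as a negative control: reflexive tachycardia makes the
HR-SBP relationship inconsistent across subjects, so PTT must outperform HR
for the averaged-regression methodology to be meaningful.

Pipeline stages per subject:

1. **Record selection** — the longest record with both an ECG and an
   arterial-pressure channel (ties broken by smallest record id; subjects
   with no eligible record are dropped with a reason code).
2. **R-peak detection** — a Pan-Tompkins-style chain (5-15 Hz band-pass,
   derivative, squaring, 150 ms moving-window integration, adaptive
   double threshold, 200 ms refractory period), refined to the local raw
   maximum. No search-back pass is implemented; at the noise levels the
   generator produces, sensitivity is >= 99% without it.
3. **ABP peak pairing** — for beat *n* the systolic peak is the dominant
   local maximum (prominence >= 10 mmHg) in the window
   `(R_n + 50 ms, R_n + min(RR_n, 1000 ms))`. A second local maximum at
   >= 90% of the dominant height flags the beat *ambiguous*; no qualifying
   maximum, or a data gap inside the window, flags it *missing*. These
   window constants cover the physiological PTT-RA range (roughly 280-370
   ms) with margin and are configurable (`DetectionConfig`). The 90%
   two-maximum rule is this package's operational definition of an
   ambiguous peak; the simulator creates exactly that condition.
4. **ECG signal quality (ESQI)** — windows of +/-60 ms around each R-peak
   are correlated against their pointwise median template; the score is the
   mean Pearson correlation with negatives clipped to zero, in [0, 1],
   invariant to ECG gain and offset. The statistic (median template, mean
   clipped r, +/-60 ms window) is this package's concrete definition of a
   QRS-intercorrelation quality index; all three choices are configurable.
5. **Beat features and averaging** — PTT-RA, RR, HR = 60000/RR, SBP per
   beat; series split into contiguous runs of clean beats, each run smoothed
   independently, half-window edges dropped (never extrapolated), gaps never
   interpolated.
6. **Event screening** — an event is averaged SBP falling to <= 90 mmHg
   within 15 min of being >= 120 mmHg. The scanner anchors on each
   down-crossing of 90 mmHg, starts the segment at the last >= 120 mmHg
   beat before it (boundary-inclusive 900 s window), and ends it at the
   nadir before averaged SBP re-rises above 90; candidates never overlap.
   Screening order: SBP bounds, length >= 21 heartbeats, ESQI >= 0.9,
   missing/ambiguous peaks (zero in strict mode, < 5 in relaxed mode), with
   the first failure recorded as the exclusion reason. ESQI and the bad-peak
   count refer to the segment span only. Where a subject has several
   included segments, the highest-ESQI one is primary and the runner-up
   secondary (earlier segment wins ties).
7. **Regression and aggregation** — per-segment OLS of SBP_AV on PTT-RA_AV
   and on HR_AV, plus raw (unaveraged) variants; cohort medians and IQRs
   (linear-interpolation percentiles) of r and slope; count of positive-r
   subjects; Bland-Altman agreement of primary-vs-secondary slopes (bias
   +/- 1.96 x sample SD, n-1) with the fraction of sign flips in r.
   Degenerate fits (zero predictor variance) are excluded from summaries
   and counted.

## The waveform generator

The generator is a stand-in for raw ICU data, not a hemodynamic model: the
real study is observational and specifies no generative process, so every
construction here is a declared convention, built to contain exactly the
structure the pipeline is sensitive to.

* **Beat train** — instantaneous HR = mean (85 bpm) + respiratory sinus
  arrhythmia (2.5 bpm at 15 breaths/min); beat times integrate this rate.
  Optionally (`hr_coupling="baroreflex"`) HR also rises 0.3 bpm per mmHg of
  SBP drop; the default (`independent`) leaves HR uninformative about SBP,
  which is what makes the HR negative control meaningful.
* **SBP trajectory** — baseline 125 mmHg with half-cosine declines to a
  nadir of 85 mmHg over 300 s (values chosen to sit inside the reported
  event statistics of the motivating ICU cohort: max ~123, nadir ~88,
  duration ~287 s), a 60 s nadir hold and a 180 s recovery; two episodes
  per 1500 s record by default so the repeated-event (Bland-Altman)
  analysis is exercised. A respiratory oscillation (4 mmHg, offset pi/2
  from the RSA phase) and per-beat Gaussian noise (3 mmHg) are added.
* **PTT** — per-subject slope alpha ~ Normal(-1.23, 0.4) mmHg/ms (magnitude
  floored at 0.2: the inverted law is non-physiological near zero; ~0.5% of
  draws are affected), intercept fixed by PTT = 320 ms at baseline SBP.
  Each beat's PTT inverts the linear law, adds 4 ms measurement noise, and
  the rendered delay is rounded to the 125 Hz sample grid — raw PTT is
  therefore an exact multiple of 8 ms, as in real monitor exports.
* **Waveforms** — fixed analytic templates: a biphasic QRS spike with a
  small T wave; an arterial pulse with a 120 ms half-cosine upstroke and
  exponential (tau = 300 ms) decay, scaled so the rendered maximum equals
  that beat's SBP exactly (pulse pressure fixed at 45 mmHg). Morphological
  realism is deliberately minimal — the detectors consume peak positions
  and values only.
* **Artifacts** — per beat, with probability 0.001 each: *missing* (no
  pulse rendered) or *ambiguous* (a Gaussian bump at 97% of pulse height,
  180 ms after the systolic peak, inside the search window).
* **Determinism** — one RNG stream per subject, seeded by
  `(cohort_seed, subject_index)`, so any subject is reproducible in
  isolation and cohorts are order-independent.

What the generator does **not** emulate: pacemaker spikes, arrhythmia, PPG
channels, waveform desynchronization, drift in the PTT-SBP relationship,
nonlinearity at extreme pressures, or clustered (rather than independent)
artifacts. Passing recovery tests therefore shows the pipeline is correct
and unbiased under its stated model; it does not certify performance on
real ICU recordings, where detection failure modes dominate.

## Numerical choices and degenerate inputs

* Savitzky-Golay coefficients come from the standard closed form; the test
  suite checks them against a direct per-window least-squares oracle at
  1e-9. Runs shorter than the window produce no output rather than padded
  estimates.
* The 15-minute event window is 900.0 s of wall-clock beat-timestamp time,
  boundary inclusive. Nadir ties take the earliest beat.
* IQRs use linear interpolation between order statistics.
* Flat or all-gap ECG yields an empty R-peak series; fewer than 3 usable
  QRS windows yields ESQI 0 with a warning; constant predictors yield a
  flagged degenerate fit, excluded and counted in summaries.
* WFDB output uses format 16 (int16, adaptive gain, -32768 as the gap
  marker), so writing is lossy below half an LSB; a second write/read cycle
  is exact. The CSV fixture format round-trips float64 exactly.

## Known limitations

* **Sample-grid resolution bounds attainable correlation.** At 125 Hz the
  8 ms PTT grid leaves residual variance of about (8^2/12)/k ms^2 after
  k-fold effective averaging. Over a typical screened segment (averaged SBP
  120 -> 85 mmHg) this caps noise-free per-subject |r| near 0.998-0.9995,
  the cap tightening as the slope magnitude grows (steeper slopes compress
  the PTT sweep toward the grid). Recovered slopes remain unbiased to
  within ~0.02 mmHg/ms because the quantization error is nearly
  conditionally centered over a sweeping ramp. The same resolution limit
  attenuates the raw (unaveraged) correlations relative to the averaged
  ones.
* The R-peak detector omits the search-back stage and is tuned for
  template-shaped, upright QRS complexes.
* Run-splitting around flagged beats (rather than interpolation) is a
  conservative convention; in relaxed mode it shortens averaged series
  near artifacts.
* Cohort-level outputs of the simulated study are *not* expected to
  reproduce any real cohort's numbers; they verify internal consistency
  and recovery of known ground truth at desk scale.
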