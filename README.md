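# pttrack

Pulse-transit-time tracking of systolic blood pressure during rapid
hypotensive episodes.

## The problem

Continuous blood-pressure monitoring is invasive (an arterial line), so most
hospitalized patients get intermittent cuff readings and significant
hypotensive episodes can go unnoticed. Pulse transit time — here **PTT-RA**,
the interval from the ECG R-wave to the paired arterial systolic peak — is a
candidate surrogate: pulse-wave velocity rises with pressure, so PTT should
lengthen as pressure falls. `pttrack` implements, as a tested and reusable
pipeline, the analysis needed to ask whether PTT-RA trends track systolic
blood pressure (SBP) trends during rapid declines (averaged SBP falling from
≥ 120 mmHg to ≤ 90 mmHg within 15 minutes):

* reading multi-channel waveform records (WFDB format-16 or a CSV fixture
  format) and selecting the longest eligible record per subject;
* Pan-Tompkins-style R-peak detection, R-anchored arterial-peak pairing
  with *missing*/*ambiguous* flagging, and a QRS-intercorrelation ECG
  signal-quality index (ESQI);
* per-beat variables (PTT-RA, RR, HR, SBP) and their order-1, width-21
  Savitzky-Golay moving averages;
* hypotension-event scanning with the inclusion criteria (SBP bounds,
  ≥ 21 heartbeats, ESQI ≥ 0.9, zero — or, relaxed, < 5 — bad peaks) and
  highest-ESQI primary/secondary segment selection per subject;
* per-subject OLS of SBP_AV on PTT-RA_AV (`SBP_AV = α₁·PTT-RA_AV + β₁`)
  and on HR_AV as a negative control (`SBP_AV = α₂·HR_AV + β₂`), raw
  unaveraged variants, cohort median/IQR summaries, and Bland-Altman
  agreement of slopes across repeated events;
* a waveform **simulator** with known SBP-PTT coupling (per-subject slope,
  respiratory oscillations of HR and BP with a phase offset, 125 Hz
  quantization, injected missing/ambiguous peaks) providing ground truth
  for recovery tests.

It is aimed at researchers prototyping cuffless blood-pressure methods who
need a fully specified, reproducible reference implementation of this
event-based analysis, with every threshold exposed in a single config.

## Worked example

Simulate the default 50-subject cohort (two hypotensive episodes per
record, slopes drawn from Normal(−1.23, 0.4) mmHg/ms) and run the full
analysis:

```bash
pttrack all --out run/ --seed 42
```

which ends with (per-segment screening lines omitted):

```
subjects: 50
eligible records: 50
candidate segments: 100
included segments (strict): 53
  excluded [missing/ambiguous peaks]: 47
median r (SBP_AV vs PTT-RA_AV): -0.988; median slope: -1.227 mmHg/ms
```

Reading: all 100 candidate declines met the event definition, 53 survived
the strict zero-bad-peaks screen, and across included subjects the averaged
SBP-PTT relationship is strongly negative (median Pearson r −0.988) with a
median slope of −1.227 mmHg per ms — each millisecond of PTT lengthening
corresponds to roughly 1.2 mmHg of SBP decline, close to this cohort's
simulated median. `run/` contains the event table, per-subject regressions,
cohort summary JSON, the inclusion-flow audit, and figures (r histograms,
slope fan, a median-subject panel, the Bland-Altman plot).

The same pipeline runs on existing records
(`pttrack analyze --records dir/ --out run/`), and the library surface
(`simulate_subject`, `detect_r_peaks`, `scan_events`, `fit_subject`, ...)
is importable directly; see `docs/methods.md` for the model, the
generator's assumptions, and known limitations.

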