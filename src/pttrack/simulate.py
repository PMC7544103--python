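"""Synthetic paired ECG/ABP records with known SBP-PTT coupling.

The generator stands in for raw ICU waveform data: no mechanistic
hemodynamics, just the structure the downstream analysis is sensitive to.
Per subject it produces

* a beat train whose instantaneous heart rate carries respiratory sinus
  arrhythmia (and, optionally, a baroreflex response to falling pressure);
* a systolic-pressure trajectory with one or more hypotensive episodes
  (smooth half-cosine ramp from baseline to nadir, a nadir hold, recovery),
  plus a respiration-driven oscillation offset in phase from the heart-rate
  oscillation, plus beat-to-beat noise;
* a pulse transit time obtained by inverting the per-subject linear law
  ``SBP = alpha * PTT + beta`` and adding measurement noise; the rendered
  ABP delay is quantized to the sample grid (8 ms at 125 Hz), mirroring the
  temporal resolution of monitor exports;
* waveforms built from fixed analytic templates — a biphasic QRS spike with a
  small T wave, and an asymmetric arterial pulse (half-cosine upstroke,
  exponential decay) whose rendered maximum equals that beat's true SBP;
* injected artifacts: *missing* beats (no arterial pulse rendered) and
  *ambiguous* beats (a second local maximum at >= 90% of the true peak
  inside the systolic search window).

Everything is reproducible from ``(config.seed, subject_index)`` through a
single per-subject RNG stream.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig
from .io import WaveformRecord

ECG_CHANNEL = "ECG_II"
ABP_CHANNEL = "ABP"

FLAG_OK = "ok"
FLAG_MISSING = "missing"
FLAG_AMBIGUOUS = "ambiguous"


@dataclass
class SimulationTruth:
    """Ground truth per simulated subject, used by recovery tests."""

    subject_id: str
    true_slope: float            # alpha, mmHg/ms
    true_intercept: float        # beta, mmHg
    beat_times: np.ndarray       # s, one entry per beat
    true_sbp: np.ndarray         # mmHg per beat (as rendered at the peak)
    true_ptt: np.ndarray         # ms per beat, before grid quantization
    true_hr: np.ndarray          # beats/min per beat (from the realized RR)
    injected_flags: np.ndarray   # 'ok' | 'missing' | 'ambiguous' per beat
    event_windows: list[tuple[float, float]]  # (onset, offset) of each decline

    def __post_init__(self) -> None:
        n = len(self.beat_times)
        for name in ("true_sbp", "true_ptt", "true_hr", "injected_flags"):
            if len(getattr(self, name)) != n:
                raise ValueError("truth arrays must share one length")

    @property
    def event_window(self) -> tuple[float, float]:
        return self.event_windows[0]

    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beat_time_s": self.beat_times,
                "true_sbp": self.true_sbp,
                "true_ptt_ms": self.true_ptt,
                "true_hr": self.true_hr,
                "injected_flag": self.injected_flags,
            }
        )


def _sbp_trajectory(t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Deterministic SBP baseline curve (no respiration, no noise)."""
    sbp = np.full_like(t, config.sbp_baseline, dtype=float)
    drop = config.sbp_baseline - config.sbp_nadir
    for onset in config.event_onsets():
        ramp_end = onset + config.ramp_duration
        hold_end = ramp_end + config.nadir_hold
        rec_end = hold_end + config.recovery_duration
        m = (t >= onset) & (t < ramp_end)
        sbp[m] = config.sbp_baseline - drop * 0.5 * (
            1.0 - np.cos(np.pi * (t[m] - onset) / config.ramp_duration)
        )
        m = (t >= ramp_end) & (t < hold_end)
        sbp[m] = config.sbp_nadir
        m = (t >= hold_end) & (t < rec_end)
        sbp[m] = config.sbp_nadir + drop * 0.5 * (
            1.0 - np.cos(np.pi * (t[m] - hold_end) / config.recovery_duration)
        )
    return sbp


def _instantaneous_hr(t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    f_resp = config.resp_rate / 60.0
    hr = config.mean_hr + config.rsa_depth * np.sin(2.0 * np.pi * f_resp * t)
    if config.hr_coupling == "baroreflex":
        hr = hr + config.baroreflex_gain * (
            config.sbp_baseline - _sbp_trajectory(np.atleast_1d(t), config)
        )
    return hr


def _beat_times(config: SimulationConfig) -> np.ndarray:
    times = []
    t = 1.0
    limit = config.record_duration - 1.5
    while t < limit:
        times.append(t)
        hr = float(_instantaneous_hr(np.array([t]), config)[0])
        hr = max(hr, 20.0)
        t += 60.0 / hr
    return np.asarray(times)


def _ecg_template(fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample offsets and values of one beat's ECG shape, R peak at offset 0."""
    off = np.arange(int(round(-0.10 * fs)), int(round(0.35 * fs)) + 1)
    tau = off / fs
    v = (
        1.0 * np.exp(-0.5 * (tau / 0.012) ** 2)          # R
        - 0.15 * np.exp(-0.5 * ((tau + 0.035) / 0.010) ** 2)  # Q
        - 0.25 * np.exp(-0.5 * ((tau - 0.030) / 0.012) ** 2)  # S
        + 0.20 * np.exp(-0.5 * ((tau - 0.250) / 0.050) ** 2)  # T
    )
    return off, v


def _subject_rng(config: SimulationConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, int(subject_index)])


def draw_subject_slope(config: SimulationConfig, subject_index: int) -> float:
    """The per-subject SBP-PTT slope draw (first value of the subject stream)."""
    rng = _subject_rng(config, subject_index)
    alpha = config.true_slope_mean + config.true_slope_sd * rng.standard_normal()
    if config.true_slope_mean < 0:
        # the inverted law PTT=(SBP-beta)/alpha is non-physiological near
        # alpha=0; floor the magnitude (affects ~0.5% of default draws)
        alpha = min(alpha, -0.2)
    elif alpha == 0.0:
        raise ConfigurationError("drawn slope is zero; SBP-PTT law not invertible")
    return alpha


def simulate_subject(
    config: SimulationConfig, subject_index: int
) -> tuple[WaveformRecord, SimulationTruth]:
    """Render one subject's paired ECG/ABP record plus its ground truth."""
    config.validate()
    rng = _subject_rng(config, subject_index)
    alpha = draw_subject_slope(config, subject_index)
    rng.standard_normal()  # keep the stream aligned with the slope draw
    beta = config.sbp_baseline - alpha * config.ptt_at_baseline

    fs = config.fs
    t_beats = _beat_times(config)
    nb = len(t_beats)
    if nb < 3:
        raise ConfigurationError("record too short to contain beats")

    f_resp = config.resp_rate / 60.0
    sbp = (
        _sbp_trajectory(t_beats, config)
        + config.resp_bp_amp
        * np.sin(2.0 * np.pi * f_resp * t_beats + config.resp_phase_offset)
    )
    if config.sbp_noise_sd > 0:
        sbp = sbp + rng.normal(0.0, config.sbp_noise_sd, nb)
    ptt = (sbp - beta) / alpha
    if config.ptt_noise_sd > 0:
        ptt = ptt + rng.normal(0.0, config.ptt_noise_sd, nb)
    if np.any(ptt * fs / 1000.0 < 3):
        raise ConfigurationError("configuration produces non-physical PTT <= 3 samples")

    # truth HR is the generative instantaneous rate at each beat; the
    # RR-derived rate (what the pipeline measures) lags it by half a beat
    hr = _instantaneous_hr(t_beats, config)

    u = rng.random(nb)
    flags = np.full(nb, FLAG_OK, dtype=object)
    flags[u < config.p_missing_beat] = FLAG_MISSING
    flags[
        (u >= config.p_missing_beat)
        & (u < config.p_missing_beat + config.p_ambiguous_beat)
    ] = FLAG_AMBIGUOUS

    n = int(round(config.record_duration * fs))
    r_idx = np.round(t_beats * fs).astype(int)

    # --- ECG channel: one QRS template per beat
    ecg = np.zeros(n)
    off, tmpl = _ecg_template(fs)
    for ri in r_idx:
        lo, hi = ri + off[0], ri + off[-1] + 1
        a = max(lo, 0)
        b = min(hi, n)
        ecg[a:b] += tmpl[a - lo : b - lo]

    # --- ABP channel: one pulse per non-missing beat, maximum-combined
    dbp = sbp - config.pulse_pressure
    abp = np.full(n, float(np.min(dbp)) - 1.0)
    delay_smp = np.round(ptt * fs / 1000.0).astype(int)
    rise = int(round(0.12 * fs))
    decay_len = int(round(1.2 * fs))
    tau_decay = 0.30 * fs
    k_rise = 0.5 * (1.0 - np.cos(np.pi * np.arange(rise + 1) / rise))
    k_decay = np.exp(-np.arange(1, decay_len + 1) / tau_decay)
    bump_off = int(round(0.18 * fs))
    bump_k = np.exp(
        -0.5 * ((np.arange(-3 * 4, 3 * 4 + 1)) / (0.030 * fs)) ** 2
    )
    for i in range(nb):
        if flags[i] == FLAG_MISSING:
            continue
        peak = r_idx[i] + delay_smp[i]
        pp = sbp[i] - dbp[i]
        shape = np.concatenate([k_rise, k_decay])
        seg = dbp[i] + pp * shape
        lo = peak - rise
        a, b = max(lo, 0), min(lo + len(seg), n)
        if a >= b:
            continue
        abp[a:b] = np.maximum(abp[a:b], seg[a - lo : b - lo])
        if flags[i] == FLAG_AMBIGUOUS:
            c = peak + bump_off
            seg2 = dbp[i] + 0.97 * pp * bump_k
            lo2 = c - (len(bump_k) // 2)
            a2, b2 = max(lo2, 0), min(lo2 + len(bump_k), n)
            if a2 < b2:
                abp[a2:b2] = np.maximum(abp[a2:b2], seg2[a2 - lo2 : b2 - lo2])

    if config.ecg_noise_sd > 0:
        ecg = ecg + rng.normal(0.0, config.ecg_noise_sd, n)
    if config.abp_noise_sd > 0:
        abp = abp + rng.normal(0.0, config.abp_noise_sd, n)

    subject_id = f"S{subject_index:04d}"
    record = WaveformRecord(
        subject_id=subject_id,
        record_id=f"{subject_id}-r0",
        fs=fs,
        channels={ECG_CHANNEL: ecg, ABP_CHANNEL: abp},
        roles={"ecg": ECG_CHANNEL, "abp": ABP_CHANNEL},
        units={ECG_CHANNEL: "mV", ABP_CHANNEL: "mmHg"},
    )
    windows = [
        (onset, onset + config.ramp_duration) for onset in config.event_onsets()
    ]
    truth = SimulationTruth(
        subject_id=subject_id,
        true_slope=alpha,
        true_intercept=beta,
        beat_times=t_beats,
        true_sbp=sbp,
        true_ptt=ptt,
        true_hr=hr,
        injected_flags=flags,
        event_windows=windows,
    )
    return record, truth


def simulate_cohort(
    config: SimulationConfig,
) -> list[tuple[WaveformRecord, SimulationTruth]]:
    """Simulate ``config.n_subjects`` independent subjects.

    Each subject's stream is derived from ``(config.seed, subject_index)``,
    so cohort members are reproducible individually and independent of each
    other; slopes are therefore i.i.d. Normal(true_slope_mean, true_slope_sd)
    draws under the cohort seed.
    """
    config.validate()
    return [simulate_subject(config, i) for i in range(config.n_subjects)]
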