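"""ECG R-peak detection, paired ABP systolic-peak search, and ECG quality.

The R-peak detector is a Pan-Tompkins-style chain: band-pass (5-15 Hz)
-> derivative -> squaring -> moving-window integration -> adaptive
double-threshold with a 200 ms refractory period, followed by refinement of
each detection to the local raw-signal maximum. ABP systolic peaks are then
searched beat-by-beat in a window anchored on each R-peak, and every beat is
flagged ``ok``, ``missing`` (no sufficiently prominent pulse, or the window
touches a gap) or ``ambiguous`` (a competing local maximum at >= 90% of the
dominant peak height).

The ECG signal quality index (ESQI) scores QRS self-similarity: windows of
+/-60 ms around each R-peak are correlated against their pointwise median
template; the score is the mean Pearson correlation with negative values
clipped to zero, hence lies in [0, 1] and is invariant to amplitude scaling
and offset of the ECG.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import DetectionConfig

FLAG_OK = "ok"
FLAG_MISSING = "missing"
FLAG_AMBIGUOUS = "ambiguous"


@dataclass
class RPeakSeries:
    """Sample positions of detected R-waves (strictly increasing)."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and np.any(np.diff(self.indices) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs

    def rr_ms(self) -> np.ndarray:
        """Forward inter-beat interval in ms; the last beat gets the median."""
        if len(self) < 2:
            return np.full(len(self), np.nan)
        d = np.diff(self.indices) / self.fs * 1000.0
        return np.append(d, np.median(d))


@dataclass
class AbpPeakSeries:
    """Per-beat ABP systolic peak positions and quality flags.

    Index-aligned with the R-peak series that produced it: entry *n* pairs the
    nth R-wave with the nth arterial peak. Missing beats hold index -1.
    """

    indices: np.ndarray
    flags: np.ndarray
    fs: float = 0.0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.flags = np.asarray(self.flags, dtype=object)
        if len(self.indices) != len(self.flags):
            raise ValueError("indices and flags must be aligned")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class EsqiScore:
    """ECG signal quality index in [0, 1]."""

    value: float
    n_beats: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("ESQI must lie in [0, 1]")

    def __float__(self) -> float:
        return self.value


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    sos = sps.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_r_peaks(
    ecg: np.ndarray, fs: float, config: DetectionConfig | None = None
) -> RPeakSeries:
    """Detect one index per QRS complex with a >= 200 ms refractory period.

    Gaps (NaN) are treated as silence; a flat or all-gap trace yields an
    empty series.
    """
    config = config or DetectionConfig()
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < int(2 * fs):
        raise ValueError("need at least 2 s of ECG")
    finite = np.isfinite(ecg)
    if not finite.any():
        return RPeakSeries(np.empty(0, dtype=int), fs)
    x = np.where(finite, ecg, 0.0)
    x = x - np.median(x[finite])
    if np.max(np.abs(x[finite])) < 1e-12:
        return RPeakSeries(np.empty(0, dtype=int), fs)

    bp = _bandpass(x, fs, config.bandpass_low, config.bandpass_high)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(int(round(config.integration_window * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refract = max(int(round(config.refractory * fs)), 1)
    cand, _ = sps.find_peaks(integ, distance=refract)
    if cand.size == 0:
        return RPeakSeries(np.empty(0, dtype=int), fs)

    # adaptive double estimate of signal vs noise peak level
    head = cand[cand < int(2.5 * fs)]
    spki = float(np.max(integ[head])) * 0.6 if head.size else float(np.max(integ)) * 0.3
    npki = float(np.median(integ)) if np.isfinite(np.median(integ)) else 0.0
    accepted = []
    for c in cand:
        thr = npki + 0.25 * (spki - npki)
        if integ[c] > thr:
            accepted.append(c)
            spki = 0.125 * integ[c] + 0.875 * spki
        else:
            npki = 0.125 * integ[c] + 0.875 * npki

    # refine each detection to the raw-signal maximum nearby
    half = int(round(0.10 * fs))
    refined = []
    for c in accepted:
        a, b = max(c - half, 0), min(c + half + 1, len(ecg))
        seg = ecg[a:b]
        if not np.isfinite(seg).any():
            continue
        refined.append(a + int(np.nanargmax(seg)))
    refined = np.unique(refined).astype(int)

    # enforce refractory after refinement, keeping the taller of close pairs
    keep: list[int] = []
    for r in refined:
        if keep and r - keep[-1] < refract:
            if ecg[r] > ecg[keep[-1]]:
                keep[-1] = r
        else:
            keep.append(r)
    return RPeakSeries(np.asarray(keep, dtype=int), fs)


def detect_abp_peaks(
    abp: np.ndarray,
    r_peaks: RPeakSeries,
    rr_ms: np.ndarray | None = None,
    config: DetectionConfig | None = None,
) -> AbpPeakSeries:
    """Locate the arterial systolic peak paired with each R-wave.

    For beat *n* the search window is ``(R_n + w_min, R_n + min(RR_n, w_max))``.
    The dominant local maximum (prominence >= ``abp_prominence``) is the peak;
    a second local maximum at >= ``ambiguity_ratio`` of the dominant height
    flags the beat ambiguous; no qualifying maximum, or a gap inside the
    window, flags it missing.
    """
    config = config or DetectionConfig()
    if len(r_peaks) == 0:
        raise ValueError("r_peaks must be nonempty")
    abp = np.asarray(abp, dtype=float)
    fs = r_peaks.fs
    if rr_ms is None:
        rr_ms = r_peaks.rr_ms()
    rr_ms = np.asarray(rr_ms, dtype=float)

    n = len(r_peaks)
    out_idx = np.full(n, -1, dtype=int)
    out_flag = np.full(n, FLAG_MISSING, dtype=object)
    w_min_smp = int(round(config.w_min * fs))
    for i, r in enumerate(r_peaks.indices):
        rr_s = rr_ms[i] / 1000.0 if np.isfinite(rr_ms[i]) else config.w_max
        hi = r + int(round(min(rr_s, config.w_max) * fs))
        lo = r + w_min_smp
        lo, hi = max(lo, 0), min(hi, len(abp))
        if hi - lo < 3:
            continue
        window = abp[lo:hi]
        if not np.isfinite(window).all():
            continue  # gap overlap -> missing
        peaks, props = sps.find_peaks(window, prominence=config.abp_prominence)
        if peaks.size == 0:
            continue
        heights = window[peaks]
        k = int(np.argmax(heights))
        out_idx[i] = lo + peaks[k]
        others = np.delete(heights, k)
        if others.size and np.max(others) >= config.ambiguity_ratio * heights[k]:
            out_flag[i] = FLAG_AMBIGUOUS
        else:
            out_flag[i] = FLAG_OK
    return AbpPeakSeries(out_idx, out_flag, fs=fs)


def compute_esqi(
    ecg: np.ndarray,
    r_peaks: RPeakSeries,
    fs: float | None = None,
    config: DetectionConfig | None = None,
) -> EsqiScore:
    """QRS intercorrelation quality score in [0, 1]."""
    config = config or DetectionConfig()
    fs = fs or r_peaks.fs
    ecg = np.asarray(ecg, dtype=float)
    half = int(config.esqi_half_width * fs)
    windows = []
    for r in r_peaks.indices:
        a, b = r - half, r + half + 1
        if a < 0 or b > len(ecg):
            continue
        seg = ecg[a:b]
        if np.isfinite(seg).all():
            windows.append(seg)
    if len(windows) < 3:
        warnings.warn("fewer than 3 usable QRS windows; ESQI set to 0")
        return EsqiScore(0.0, n_beats=len(windows))
    w = np.asarray(windows)
    template = np.median(w, axis=0)
    t_c = template - template.mean()
    t_norm = np.sqrt(np.sum(t_c**2))
    scores = np.zeros(len(w))
    if t_norm > 0:
        w_c = w - w.mean(axis=1, keepdims=True)
        w_norm = np.sqrt(np.sum(w_c**2, axis=1))
        valid = w_norm > 0
        scores[valid] = (w_c[valid] @ t_c) / (w_norm[valid] * t_norm)
    scores = np.clip(scores, 0.0, 1.0)
    return EsqiScore(float(np.mean(scores)), n_beats=len(w))
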