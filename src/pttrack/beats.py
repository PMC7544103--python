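"""Per-beat variables and their Savitzky-Golay moving averages.

From index-aligned R-peak / ABP-peak series this module builds the per-beat
table — pulse transit time PTT-RA (R-wave to arterial peak, ms), RR interval
(ms), heart rate (60000/RR, beats/min) and systolic pressure SBP (the ABP
sample value at the detected peak, mmHg) — and smooths each series with a
centered first-order Savitzky-Golay filter of width 21 beats (a straight-line
fit through the 10 preceding and 10 following heartbeats, evaluated at the
center).

Averaged values exist only where a full window of clean beats is available:
beat series are split into contiguous runs of ``ok`` beats, each run is
smoothed independently, and the first/last half-window of every run is
dropped rather than extrapolated. Gaps are never interpolated across.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs

from .config import AveragingConfig
from .io import WaveformRecord
from .peaks import FLAG_OK, AbpPeakSeries, RPeakSeries

BEAT_COLUMNS = [
    "beat_index",
    "r_sample",
    "abp_sample",
    "time_s",
    "ptt_ra",
    "rr",
    "hr",
    "sbp",
    "flag",
]


def extract_beat_table(
    record: WaveformRecord,
    r_peaks: RPeakSeries,
    abp_peaks: AbpPeakSeries,
) -> pd.DataFrame:
    """Build the per-beat variable table from aligned peak series.

    ``ptt_ra = (abp_sample - r_sample) / fs * 1000`` ms; ``rr`` is the
    backward R-R interval (undefined for the first beat); ``hr = 60000/rr``.
    Values for beats not flagged ``ok`` are NaN, the flag is preserved.
    """
    if len(r_peaks) != len(abp_peaks):
        raise ValueError("peak series must be index-aligned")
    fs = record.fs
    abp = record.channel("abp")
    r = r_peaks.indices.astype(float)
    a = abp_peaks.indices.astype(float)
    ok = np.asarray([f == FLAG_OK for f in abp_peaks.flags])

    ptt = np.where(ok, (a - r) / fs * 1000.0, np.nan)
    rr = np.concatenate([[np.nan], np.diff(r)]) / fs * 1000.0
    hr = 60000.0 / rr
    sbp = np.full(len(r), np.nan)
    ok_idx = abp_peaks.indices[ok]
    sbp[ok] = abp[ok_idx]

    return pd.DataFrame(
        {
            "beat_index": np.arange(len(r)),
            "r_sample": r_peaks.indices,
            "abp_sample": abp_peaks.indices,
            "time_s": r_peaks.indices / fs,
            "ptt_ra": ptt,
            "rr": rr,
            "hr": hr,
            "sbp": sbp,
            "flag": abp_peaks.flags,
        }
    )


def savgol_average(
    series: np.ndarray, width: int = 21, order: int = 1
) -> np.ndarray:
    """Centered Savitzky-Golay smoothing of one contiguous beat series.

    Returns only the central values: for an input of length *n* the output
    has length ``n - width + 1`` (empty when ``n < width``). With ``order=1``
    each output value is the least-squares straight line through its window,
    evaluated at the window center, so linear inputs are reproduced exactly.
    """
    x = np.asarray(series, dtype=float)
    if width % 2 != 1 or width < 3:
        raise ValueError("width must be an odd integer >= 3")
    if order >= width:
        raise ValueError("order must be below width")
    if len(x) < width:
        return np.empty(0)
    if not np.isfinite(x).all():
        raise ValueError("savgol_average requires a gap-free run")
    coeffs = savgol_coeffs(width, order, use="dot")
    windows = np.lib.stride_tricks.sliding_window_view(x, width)
    return windows @ coeffs


def _ok_runs(beats: pd.DataFrame) -> list[np.ndarray]:
    """Positions (row numbers) of maximal contiguous runs of complete beats.

    A beat is complete when its flag is ``ok`` and all averaged quantities
    (ptt_ra, sbp, hr) are finite — the first beat of a record, whose RR is
    undefined, is therefore never part of a run.
    """
    complete = (
        (beats["flag"] == FLAG_OK).to_numpy()
        & np.isfinite(beats["ptt_ra"].to_numpy(dtype=float))
        & np.isfinite(beats["sbp"].to_numpy(dtype=float))
        & np.isfinite(beats["hr"].to_numpy(dtype=float))
    )
    runs = []
    pos = np.flatnonzero(complete)
    if pos.size == 0:
        return runs
    splits = np.flatnonzero(np.diff(pos) > 1)
    for chunk in np.split(pos, splits + 1):
        runs.append(chunk)
    return runs


def build_averaged_table(
    beats: pd.DataFrame, config: AveragingConfig | None = None
) -> pd.DataFrame:
    """Savitzky-Golay averages of sbp/ptt_ra/hr over each clean run.

    Output rows are the central beats of every contiguous run of at least
    ``width`` complete beats, with columns ``beat_index``, ``time_s``,
    ``sbp_av``, ``ptt_ra_av`` and ``hr_av``. A table with no qualifying run
    is empty (the segment will later fail the minimum-length criterion).
    """
    config = config or AveragingConfig()
    width, order = config.width, config.order
    half = width // 2
    frames = []
    for run in _ok_runs(beats):
        if len(run) < width:
            continue
        sub = beats.iloc[run]
        frames.append(
            pd.DataFrame(
                {
                    "beat_index": sub["beat_index"].to_numpy()[half:-half],
                    "time_s": sub["time_s"].to_numpy()[half:-half],
                    "sbp_av": savgol_average(sub["sbp"].to_numpy(), width, order),
                    "ptt_ra_av": savgol_average(
                        sub["ptt_ra"].to_numpy(), width, order
                    ),
                    "hr_av": savgol_average(sub["hr"].to_numpy(), width, order),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["beat_index", "time_s", "sbp_av", "ptt_ra_av", "hr_av"]
        )
    return pd.concat(frames, ignore_index=True)
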