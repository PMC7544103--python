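"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pttrack.config import PipelineConfig, SimulationConfig

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")

logging.disable(logging.INFO)


def quiet_sim_config(**kw) -> SimulationConfig:
    """A short, noise-free, artifact-free single-event record."""
    base = dict(
        n_subjects=1,
        sbp_noise_sd=0.0,
        ptt_noise_sd=0.0,
        ecg_noise_sd=0.0,
        abp_noise_sd=0.0,
        p_missing_beat=0.0,
        p_ambiguous_beat=0.0,
        n_events=1,
        record_duration=400.0,
        ramp_onset=80.0,
        ramp_duration=150.0,
        nadir_hold=40.0,
        recovery_duration=80.0,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def quiet_subject():
    from pttrack.simulate import simulate_subject

    return simulate_subject(quiet_sim_config(), 0)


# ---------------------------------------------------------------------------
# Independent oracles


def savgol_oracle(x: np.ndarray, width: int, order: int) -> np.ndarray:
    """Per-window polynomial least squares, evaluated at the window center."""
    x = np.asarray(x, dtype=float)
    half = width // 2
    out = []
    pos = np.arange(width) - half
    for j in range(len(x) - width + 1):
        coef = np.polyfit(pos, x[j : j + width], order)
        out.append(np.polyval(coef, 0.0))
    return np.asarray(out)


def brute_force_events(
    t: np.ndarray,
    sbp: np.ndarray,
    high: float = 120.0,
    low: float = 90.0,
    window: float = 900.0,
) -> list[tuple[int, int]]:
    """Exhaustive event search over all (start, crossing) beat pairs.

    Returns (start_row, end_row) pairs under the same segment convention as
    the scanner: a candidate anchors on each >90 -> <=90 down-crossing with
    some >=high beat within `window` seconds before it (and after the
    previous candidate), starts at the last such beat, and ends at the first
    minimum of the <=low episode.
    """
    n = len(sbp)
    out: list[tuple[int, int]] = []
    pos = 0
    j = 0
    while j < n:
        crossing = sbp[j] <= low and (j == 0 or sbp[j - 1] > low)
        if j < pos or not crossing:
            j += 1
            continue
        m = j
        while m + 1 < n and sbp[m + 1] <= low:
            m += 1
        starts = [
            i
            for i in range(pos, j)
            if sbp[i] >= high and 0 <= t[j] - t[i] <= window
        ]
        if not starts:
            j = m + 1
            continue
        i0 = starts[-1]
        e = min(range(j, m + 1), key=lambda k: (sbp[k], k))
        out.append((i0, e))
        pos = e + 1
        j = e + 1
    return out


def random_sbp_trace(rng: np.random.Generator, max_beats: int = 2000):
    """A randomized piecewise SBP_AV-like trace with plausible beat times."""
    n = int(rng.integers(30, max_beats + 1))
    n_knots = int(rng.integers(2, 9))
    knots = np.sort(rng.integers(0, n, n_knots))
    knots = np.unique(np.concatenate([[0], knots, [n - 1]]))
    levels = rng.uniform(75.0, 140.0, len(knots))
    sbp = np.interp(np.arange(n), knots, levels)
    sbp = sbp + rng.normal(0.0, 1.5, n)
    dt = rng.uniform(0.5, 1.1, n)
    t = np.cumsum(dt)
    return pd.DataFrame(
        {"beat_index": np.arange(n), "time_s": t, "sbp_av": sbp}
    )
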