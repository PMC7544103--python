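"""Per-subject linear models, cohort summaries and Bland-Altman agreement.

For each included segment, averaged SBP is regressed on averaged PTT-RA
(``SBP_AV = alpha1 * PTT-RA_AV + beta1``) and, as a negative control, on
averaged heart rate (``SBP_AV = alpha2 * HR_AV + beta2``); a raw per-beat
variant skips the averaging. Cohort results are summarized as medians with
interquartile ranges (linear-interpolation percentiles) plus the count of
subjects with positive correlation. Repeated-event stability is assessed by
Bland-Altman analysis of primary-vs-secondary slopes: mean bias and 95%
limits of agreement (bias +/- 1.96 * sample SD of the differences).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import FLAG_OK

PREDICTORS = ("ptt_ra_av", "hr_av", "ptt_ra_raw", "hr_raw")


@dataclass
class RegressionResult:
    """One ordinary-least-squares fit of SBP on a single predictor."""

    subject_id: str
    predictor: str
    slope: float          # mmHg/ms (PTT) or mmHg per beat/min (HR)
    intercept: float      # mmHg
    pearson_r: float
    n_beats: int
    degenerate: bool = False


@dataclass
class BlandAltmanResult:
    """Agreement of paired slope estimates from repeated events."""

    mean_bias: float      # mmHg/ms
    loa_low: float
    loa_high: float
    n_pairs: int
    sign_flip_fraction: float


def fit_subject(
    x: np.ndarray,
    y: np.ndarray,
    subject_id: str = "",
    predictor: str = "",
) -> RegressionResult:
    """OLS fit of ``y`` (SBP) on ``x`` with the paired Pearson correlation.

    Non-finite pairs are dropped. A predictor with zero variance yields a
    flagged degenerate result (NaN slope) instead of an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if len(x) < 2:
        raise ValueError("need at least 2 finite pairs")
    if np.ptp(x) == 0.0:
        return RegressionResult(
            subject_id, predictor, np.nan, np.nan, np.nan, len(x), degenerate=True
        )
    fit = stats.linregress(x, y)
    return RegressionResult(
        subject_id,
        predictor,
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue),
        len(x),
    )


def run_raw_variant(
    beats: pd.DataFrame,
    segment_start: int,
    segment_end: int,
    predictor: str = "ptt_ra",
    subject_id: str = "",
) -> RegressionResult:
    """Regression on the unaveraged per-beat series inside a segment span."""
    span = beats[
        (beats["beat_index"] >= segment_start)
        & (beats["beat_index"] <= segment_end)
        & (beats["flag"] == FLAG_OK)
    ]
    return fit_subject(
        span[predictor].to_numpy(dtype=float),
        span["sbp"].to_numpy(dtype=float),
        subject_id=subject_id,
        predictor=f"{predictor}_raw",
    )


def _median_iqr(v: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.percentile(v, [25.0, 50.0, 75.0])
    return float(med), float(lo), float(hi)


def summarize_cohort(results: list[RegressionResult]) -> dict[str, dict]:
    """Median/IQR of r and slope per predictor, with positive-r counts.

    Degenerate fits are excluded from the statistics; their count is
    reported per predictor.
    """
    if not results:
        raise ValueError("no regression results to summarize")
    out: dict[str, dict] = {}
    by_pred: dict[str, list[RegressionResult]] = {}
    for res in results:
        by_pred.setdefault(res.predictor, []).append(res)
    for pred, group in by_pred.items():
        valid = [g for g in group if not g.degenerate]
        n_degen = len(group) - len(valid)
        if not valid:
            out[pred] = {"n": 0, "n_degenerate": n_degen}
            continue
        r = np.array([g.pearson_r for g in valid])
        slope = np.array([g.slope for g in valid])
        med_r, r_lo, r_hi = _median_iqr(r)
        med_s, s_lo, s_hi = _median_iqr(slope)
        n_pos = int((r > 0).sum())
        out[pred] = {
            "n": len(valid),
            "n_degenerate": n_degen,
            "median_r": med_r,
            "iqr_r": (r_lo, r_hi),
            "median_slope": med_s,
            "iqr_slope": (s_lo, s_hi),
            "n_positive_r": n_pos,
            "frac_positive_r": n_pos / len(valid),
        }
    return out


def bland_altman(
    pairs: list[tuple[float, float]],
    r_pairs: list[tuple[float, float]] | None = None,
) -> BlandAltmanResult:
    """Bland-Altman agreement of paired (primary, secondary) slopes.

    Differences are primary minus secondary; limits of agreement use the
    n-1 sample standard deviation and a 1.96 multiplier. The sign-flip
    fraction counts pairs whose correlation coefficients (or, failing that,
    slopes) disagree in sign.
    """
    if len(pairs) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    arr = np.asarray(pairs, dtype=float)
    d = arr[:, 0] - arr[:, 1]
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    sign_src = np.asarray(r_pairs if r_pairs is not None else pairs, dtype=float)
    flips = np.sign(sign_src[:, 0]) != np.sign(sign_src[:, 1])
    return BlandAltmanResult(
        mean_bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n_pairs=len(d),
        sign_flip_fraction=float(np.mean(flips)),
    )


def results_to_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "predictor": r.predictor,
                "slope": r.slope,
                "intercept": r.intercept,
                "pearson_r": r.pearson_r,
                "n_beats": r.n_beats,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
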