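"""Hypotension-event scanning, inclusion criteria, and segment selection.

An event is a fall of averaged systolic pressure to <= 90 mmHg within 15
minutes (900 s) of it being >= 120 mmHg. The scanner anchors on each
down-crossing of the 90 mmHg line: if some beat at >= 120 mmHg lies within
the preceding 900 s (and after the previous event), a candidate segment is
emitted running from the LAST >= 120 mmHg beat before the crossing to the
nadir of the <= 90 mmHg episode (the minimum before averaged SBP re-rises
above 90). Candidates never overlap; scanning resumes after each one.

A candidate is then screened, in order, on: SBP bounds (max >= 120 and nadir
<= 90), segment length (>= 21 heartbeats), ECG signal quality (ESQI >= 0.9),
and peak quality (zero missing/ambiguous beats, or fewer than 5 in the
relaxed variant). When a subject has several included segments the one with
the highest ESQI is the primary and the runner-up the secondary.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EventCriteria
from .peaks import FLAG_OK

STATUS_CANDIDATE = "candidate"
STATUS_INCLUDED_STRICT = "included_strict"
STATUS_INCLUDED_RELAXED = "included_relaxed"
STATUS_EXCLUDED = "excluded"

REASON_SBP_BOUNDS = "sbp_bounds"
REASON_LENGTH = "length<21"
REASON_ESQI = "esqi<0.9"
REASON_PEAKS = "missing/ambiguous peaks"


@dataclass
class EventSegment:
    """One candidate (or screened) hypotensive episode."""

    subject_id: str
    start_beat: int          # raw beat index of the segment's first beat
    end_beat: int            # raw beat index of the nadir beat
    start_time: float        # s
    end_time: float          # s
    sbp_av_max: float        # mmHg, max averaged SBP over the span
    sbp_av_nadir: float      # mmHg, min averaged SBP over the span
    esqi: float | None = None
    n_missing_ambiguous: int | None = None
    status: str = STATUS_CANDIDATE
    exclusion_reason: str | None = None

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def n_beats(self) -> int:
        """Heartbeats spanned, boundary beats inclusive."""
        return self.end_beat - self.start_beat + 1


def scan_events(
    averaged: pd.DataFrame,
    subject_id: str = "",
    criteria: EventCriteria | None = None,
) -> list[EventSegment]:
    """Find non-overlapping candidate hypotensive declines in an averaged table.

    ``averaged`` needs columns ``beat_index``, ``time_s`` and ``sbp_av``
    (as produced by :func:`pttrack.beats.build_averaged_table`).
    """
    criteria = criteria or EventCriteria()
    if len(averaged) == 0:
        return []
    sbp = averaged["sbp_av"].to_numpy(dtype=float)
    t = averaged["time_s"].to_numpy(dtype=float)
    beat_idx = averaged["beat_index"].to_numpy(dtype=int)
    n = len(sbp)
    out: list[EventSegment] = []
    pos = 0
    j = 0
    while j < n:
        is_crossing = sbp[j] <= criteria.sbp_low and (j == 0 or sbp[j - 1] > criteria.sbp_low)
        if j < pos or not is_crossing:
            j += 1
            continue
        # candidate start: last beat at >= sbp_high within window_s before j
        lb = np.flatnonzero(
            (sbp[pos:j] >= criteria.sbp_high)
            & (t[j] - t[pos:j] <= criteria.window_s)
        )
        # end of this hypotensive episode: nadir before re-rise above sbp_low
        m = j
        while m + 1 < n and sbp[m + 1] <= criteria.sbp_low:
            m += 1
        if lb.size == 0:
            j = m + 1
            continue
        i_start = pos + int(lb[-1])
        episode = sbp[j : m + 1]
        e = j + int(np.argmin(episode))
        span = sbp[i_start : e + 1]
        out.append(
            EventSegment(
                subject_id=subject_id,
                start_beat=int(beat_idx[i_start]),
                end_beat=int(beat_idx[e]),
                start_time=float(t[i_start]),
                end_time=float(t[e]),
                sbp_av_max=float(np.max(span)),
                sbp_av_nadir=float(np.min(span)),
            )
        )
        pos = e + 1
        j = e + 1
    return out


def apply_exclusions(
    candidate: EventSegment,
    beats: pd.DataFrame,
    esqi: float,
    mode: str = "strict",
    criteria: EventCriteria | None = None,
) -> EventSegment:
    """Screen one candidate segment; returns a copy with status filled in.

    Criteria are evaluated in a fixed order — SBP bounds, segment length,
    ESQI, peak quality — and the first failure becomes the exclusion reason.
    ``esqi`` and the missing/ambiguous count refer to the candidate's beat
    span only, not the whole record.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError("mode must be 'strict' or 'relaxed'")
    criteria = criteria or EventCriteria()
    span = beats[
        (beats["beat_index"] >= candidate.start_beat)
        & (beats["beat_index"] <= candidate.end_beat)
    ]
    n_bad = int((span["flag"] != FLAG_OK).sum())
    esqi = float(esqi)
    seg = dataclasses.replace(
        candidate, esqi=esqi, n_missing_ambiguous=n_bad
    )

    reason = None
    if seg.sbp_av_max < criteria.sbp_high or seg.sbp_av_nadir > criteria.sbp_low:
        reason = REASON_SBP_BOUNDS
    elif seg.n_beats < criteria.min_beats:
        reason = REASON_LENGTH
    elif esqi < criteria.esqi_min:
        reason = REASON_ESQI
    elif (mode == "strict" and n_bad > 0) or (
        mode == "relaxed" and n_bad >= criteria.relaxed_max_missing
    ):
        reason = REASON_PEAKS

    if reason is not None:
        seg.status = STATUS_EXCLUDED
        seg.exclusion_reason = reason
    else:
        seg.status = (
            STATUS_INCLUDED_STRICT if mode == "strict" else STATUS_INCLUDED_RELAXED
        )
        seg.exclusion_reason = None
    return seg


def select_subject_segments(
    included: list[EventSegment],
) -> tuple[EventSegment, EventSegment | None]:
    """Primary = highest-ESQI segment; secondary = runner-up (if any).

    Ties are broken toward the earlier segment.
    """
    if not included:
        raise ValueError("select_subject_segments requires >= 1 included segment")
    ranked = sorted(included, key=lambda s: (-(s.esqi or 0.0), s.start_time))
    primary = ranked[0]
    secondary = ranked[1] if len(ranked) > 1 else None
    return primary, secondary


def segments_to_frame(segments: list[EventSegment]) -> pd.DataFrame:
    rows = []
    for s in segments:
        rows.append(
            {
                "subject_id": s.subject_id,
                "start_beat": s.start_beat,
                "end_beat": s.end_beat,
                "start_time_s": s.start_time,
                "end_time_s": s.end_time,
                "duration_s": s.duration,
                "n_beats": s.n_beats,
                "sbp_av_max": s.sbp_av_max,
                "sbp_av_nadir": s.sbp_av_nadir,
                "esqi": s.esqi,
                "n_missing_ambiguous": s.n_missing_ambiguous,
                "status": s.status,
                "exclusion_reason": s.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)
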