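"""Event scanning, inclusion criteria, and per-subject segment selection."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from conftest import brute_force_events, random_sbp_trace
from hypothesis import given
from hypothesis import strategies as st

from pttrack.config import EventCriteria
from pttrack.events import (
    EventSegment,
    apply_exclusions,
    scan_events,
    select_subject_segments,
)


def _trace(sbp, dt=1.0):
    sbp = np.asarray(sbp, dtype=float)
    return pd.DataFrame(
        {
            "beat_index": np.arange(len(sbp)),
            "time_s": np.arange(len(sbp)) * dt,
            "sbp_av": sbp,
        }
    )


def _beats_for(n, flags=None):
    return pd.DataFrame(
        {
            "beat_index": np.arange(n),
            "ptt_ra": np.full(n, 340.0),
            "sbp": np.full(n, 100.0),
            "hr": np.full(n, 80.0),
            "flag": flags if flags is not None else ["ok"] * n,
        }
    )


def test_single_linear_decline_yields_one_candidate():
    trace = _trace(np.linspace(125.0, 85.0, 301))  # 300 s decline
    cands = scan_events(trace, "s1")
    assert len(cands) == 1
    seg = cands[0]
    assert seg.sbp_av_max >= 120.0 and seg.sbp_av_nadir <= 90.0
    assert seg.end_time - seg.start_time <= 900.0


def test_too_slow_decline_produces_no_candidate():
    # 1300 s from 125 to 85: the last >=120 beat sits 975 s before the
    # 90-crossing, outside the 15-minute window
    trace = _trace(np.linspace(125.0, 85.0, 1301))
    assert scan_events(trace, "s1") == []
    # at exactly 900 s the window is boundary-inclusive
    trace_edge = _trace(np.linspace(125.0, 85.0, 1201))
    assert len(scan_events(trace_edge, "s1")) == 1


def test_candidate_anchors_on_last_high_beat_and_nadir():
    sbp = np.concatenate(
        [
            np.full(50, 130.0),          # high plateau
            np.linspace(130, 88, 100),   # decline, crossing inside
            np.linspace(88, 84, 20),     # keeps falling to the nadir
            np.linspace(84, 110, 30),    # re-rises above 90
            np.full(50, 110.0),
        ]
    )
    cands = scan_events(_trace(sbp), "s1")
    assert len(cands) == 1
    seg = cands[0]
    i = seg.start_beat
    assert sbp[i] >= 120.0 and np.all(sbp[i + 1 : seg.end_beat + 1] < 120.0)
    assert seg.sbp_av_nadir == pytest.approx(84.0)
    assert sbp[seg.end_beat] == pytest.approx(84.0)


def test_scanner_matches_brute_force_on_random_traces():
    rng = np.random.default_rng(1234)
    n_with_events = 0
    for _ in range(60):
        trace = random_sbp_trace(rng, max_beats=600)
        got = scan_events(trace, "s")
        want = brute_force_events(
            trace["time_s"].to_numpy(), trace["sbp_av"].to_numpy()
        )
        assert [(c.start_beat, c.end_beat) for c in got] == want
        n_with_events += bool(want)
    assert n_with_events >= 10  # the generator does exercise the scanner


@given(st.integers(0, 2**31 - 1))
def test_scanner_oracle_equivalence_property(seed):
    rng = np.random.default_rng(seed)
    trace = random_sbp_trace(rng, max_beats=250)
    got = scan_events(trace, "s")
    want = brute_force_events(
        trace["time_s"].to_numpy(), trace["sbp_av"].to_numpy()
    )
    assert [(c.start_beat, c.end_beat) for c in got] == want


def _candidate(**kw):
    base = dict(
        subject_id="s",
        start_beat=100,
        end_beat=160,
        start_time=100.0,
        end_time=160.0,
        sbp_av_max=125.0,
        sbp_av_nadir=86.0,
    )
    base.update(kw)
    return EventSegment(**base)


def test_exclusion_truth_table_flags_each_violated_criterion():
    beats = _beats_for(300)
    ok = apply_exclusions(_candidate(), beats, esqi=0.95, mode="strict")
    assert ok.status == "included_strict" and ok.exclusion_reason is None

    short = apply_exclusions(
        _candidate(end_beat=118, end_time=118.0), beats, 0.95, "strict"
    )
    assert short.status == "excluded" and short.exclusion_reason == "length<21"

    low_q = apply_exclusions(_candidate(), beats, 0.89, "strict")
    assert low_q.exclusion_reason == "esqi<0.9"

    flags = ["ok"] * 300
    flags[120] = "ambiguous"
    bad_peak = apply_exclusions(_candidate(), _beats_for(300, flags), 0.95, "strict")
    assert bad_peak.exclusion_reason == "missing/ambiguous peaks"
    assert bad_peak.n_missing_ambiguous == 1

    no_high = apply_exclusions(_candidate(sbp_av_max=119.0), beats, 0.95, "strict")
    assert no_high.exclusion_reason == "sbp_bounds"
    no_low = apply_exclusions(_candidate(sbp_av_nadir=91.0), beats, 0.95, "strict")
    assert no_low.exclusion_reason == "sbp_bounds"


def test_relaxed_mode_admits_up_to_four_bad_beats():
    flags = ["ok"] * 300
    for k in (110, 120, 130):
        flags[k] = "missing"
    beats = _beats_for(300, flags)
    strict = apply_exclusions(_candidate(), beats, 0.95, "strict")
    relaxed = apply_exclusions(_candidate(), beats, 0.95, "relaxed")
    assert strict.status == "excluded"
    assert relaxed.status == "included_relaxed"
    for k in (140, 150):
        flags[k] = "missing"
    beats5 = _beats_for(300, flags)
    assert apply_exclusions(_candidate(), beats5, 0.95, "relaxed").status == "excluded"


def test_relaxing_never_reduces_inclusions():
    rng = np.random.default_rng(99)
    for _ in range(25):
        n_bad = int(rng.integers(0, 8))
        flags = ["ok"] * 300
        for k in rng.choice(np.arange(101, 160), size=n_bad, replace=False):
            flags[int(k)] = "missing"
        beats = _beats_for(300, flags)
        esqi = float(rng.uniform(0.85, 1.0))
        strict = apply_exclusions(_candidate(), beats, esqi, "strict")
        relaxed = apply_exclusions(_candidate(), beats, esqi, "relaxed")
        if strict.status != "excluded":
            assert relaxed.status != "excluded"


def test_primary_secondary_selection_by_esqi_with_time_tiebreak():
    segs = [
        _candidate(start_time=10.0),
        _candidate(start_time=500.0),
        _candidate(start_time=900.0),
    ]
    for seg, e in zip(segs, (0.95, 0.99, 0.92)):
        seg.esqi = e
    primary, secondary = select_subject_segments(segs)
    assert primary.esqi == 0.99 and secondary.esqi == 0.95

    only, none = select_subject_segments([segs[0]])
    assert only is segs[0] and none is None

    tie = [
        dataclasses.replace(_candidate(start_time=300.0), esqi=0.95),
        dataclasses.replace(_candidate(start_time=100.0), esqi=0.95),
    ]
    primary, secondary = select_subject_segments(tie)
    assert primary.start_time == 100.0 and secondary.start_time == 300.0

    with pytest.raises(ValueError):
        select_subject_segments([])


def test_included_segments_satisfy_all_criteria_recheckably():
    crit = EventCriteria()
    trace = _trace(np.concatenate([np.full(30, 124.0), np.linspace(124, 85, 200)]))
    beats = _beats_for(len(trace))
    for cand in scan_events(trace, "s", crit):
        seg = apply_exclusions(cand, beats, 0.97, "strict", crit)
        if seg.status == "included_strict":
            assert seg.sbp_av_max >= crit.sbp_high
            assert seg.sbp_av_nadir <= crit.sbp_low
            assert seg.n_beats >= crit.min_beats
            assert seg.esqi >= crit.esqi_min
            assert seg.n_missing_ambiguous == 0
            assert seg.duration <= crit.window_s
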