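"""End-to-end orchestration: simulate/read -> detect -> average -> screen -> fit.

`run_pipeline` drives the whole analysis for a cohort (simulated, or a
directory of records), applying per-record peak detection, beat-feature
extraction, Savitzky-Golay averaging, hypotension-event screening in both
strict and relaxed modes, per-subject regressions (averaged and raw, PTT and
the HR negative control), cohort summaries and Bland-Altman agreement of
primary-vs-secondary event slopes. All tabular artifacts are written
deterministically so identical (config, seed) runs produce identical files.
"""
from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import build_averaged_table, extract_beat_table
from .config import PipelineConfig
from .events import (
    STATUS_EXCLUDED,
    EventSegment,
    apply_exclusions,
    scan_events,
    segments_to_frame,
    select_subject_segments,
)
from .io import (
    IneligibleSubjectError,
    WaveformRecord,
    read_record,
    select_longest_record,
)
from .peaks import RPeakSeries, compute_esqi, detect_abp_peaks, detect_r_peaks
from .regression import (
    RegressionResult,
    bland_altman,
    fit_subject,
    results_to_frame,
    run_raw_variant,
    summarize_cohort,
)
from .simulate import SimulationTruth, simulate_cohort

logger = logging.getLogger("pttrack")


class InclusionFlowError(RuntimeError):
    """Stage counts of the inclusion flow do not add up."""


@dataclass
class SubjectResult:
    subject_id: str
    record_id: str
    beats: pd.DataFrame | None = None
    averaged: pd.DataFrame | None = None
    candidates: list[EventSegment] = field(default_factory=list)
    segments_strict: list[EventSegment] = field(default_factory=list)
    segments_relaxed: list[EventSegment] = field(default_factory=list)
    primary: EventSegment | None = None
    secondary: EventSegment | None = None
    primary_relaxed: EventSegment | None = None
    fits: list[RegressionResult] = field(default_factory=list)
    secondary_fit: RegressionResult | None = None
    truth: SimulationTruth | None = None


@dataclass
class PipelineResult:
    subjects: list[SubjectResult]
    cohort_summaries: dict
    bland_altman: dict | None
    inclusion_flow: dict
    out_dir: Path | None = None


def _fit_averaged(
    averaged: pd.DataFrame, seg: EventSegment, predictor: str, subject_id: str
) -> RegressionResult:
    span = averaged[
        (averaged["beat_index"] >= seg.start_beat)
        & (averaged["beat_index"] <= seg.end_beat)
    ]
    return fit_subject(
        span[predictor].to_numpy(dtype=float),
        span["sbp_av"].to_numpy(dtype=float),
        subject_id=subject_id,
        predictor=predictor,
    )


def analyze_record(
    record: WaveformRecord,
    config: PipelineConfig,
    truth: SimulationTruth | None = None,
) -> SubjectResult:
    """Run the single-subject analysis chain on one waveform record."""
    res = SubjectResult(
        subject_id=record.subject_id, record_id=record.record_id, truth=truth
    )
    det, crit = config.detection, config.events
    ecg = record.channel("ecg")
    abp = record.channel("abp")
    r_peaks = detect_r_peaks(ecg, record.fs, det)
    if len(r_peaks) < 3:
        logger.info("%s: too few R-peaks detected", record.subject_id)
        return res
    abp_peaks = detect_abp_peaks(abp, r_peaks, config=det)
    res.beats = extract_beat_table(record, r_peaks, abp_peaks)
    res.averaged = build_averaged_table(res.beats, config.averaging)
    res.candidates = scan_events(res.averaged, record.subject_id, crit)

    for cand in res.candidates:
        # beat_index equals the position in the R-peak series by construction
        seg_peaks = r_peaks.indices[cand.start_beat : cand.end_beat + 1]
        esqi = (
            compute_esqi(ecg, RPeakSeries(seg_peaks, record.fs), config=det).value
            if len(seg_peaks) >= 3
            else 0.0
        )
        res.segments_strict.append(
            apply_exclusions(cand, res.beats, esqi, "strict", crit)
        )
        res.segments_relaxed.append(
            apply_exclusions(cand, res.beats, esqi, "relaxed", crit)
        )

    included = [s for s in res.segments_strict if s.status != STATUS_EXCLUDED]
    if included:
        res.primary, res.secondary = select_subject_segments(included)
        res.fits.append(
            _fit_averaged(res.averaged, res.primary, "ptt_ra_av", res.subject_id)
        )
        res.fits.append(
            _fit_averaged(res.averaged, res.primary, "hr_av", res.subject_id)
        )
        res.fits.append(
            run_raw_variant(
                res.beats,
                res.primary.start_beat,
                res.primary.end_beat,
                "ptt_ra",
                res.subject_id,
            )
        )
        res.fits.append(
            run_raw_variant(
                res.beats,
                res.primary.start_beat,
                res.primary.end_beat,
                "hr",
                res.subject_id,
            )
        )
        if res.secondary is not None:
            res.secondary_fit = _fit_averaged(
                res.averaged, res.secondary, "ptt_ra_av", res.subject_id
            )
    included_rel = [s for s in res.segments_relaxed if s.status != STATUS_EXCLUDED]
    if included_rel:
        res.primary_relaxed, _ = select_subject_segments(included_rel)
    for s in res.segments_strict:
        logger.info(
            "%s segment %.0f-%.0fs: %s%s",
            record.subject_id,
            s.start_time,
            s.end_time,
            s.status,
            f" ({s.exclusion_reason})" if s.exclusion_reason else "",
        )
    return res


def report_inclusion_flow(counts: dict) -> dict:
    """Validate and format the subject/segment inclusion flow.

    ``counts`` carries ``n_subjects``, ``n_eligible``, ``n_candidates``,
    ``n_included`` and a per-reason ``exclusions`` mapping; the candidate
    count must equal included plus all exclusions, otherwise an internal
    invariant was breached and :class:`InclusionFlowError` is raised.
    """
    excl = counts.get("exclusions", {})
    total = counts["n_included"] + sum(excl.values())
    if total != counts["n_candidates"]:
        raise InclusionFlowError(
            f"candidates={counts['n_candidates']} != included={counts['n_included']}"
            f" + exclusions={sum(excl.values())}"
        )
    lines = [
        f"subjects: {counts.get('n_subjects', 0)}",
        f"eligible records: {counts.get('n_eligible', 0)}",
        f"candidate segments: {counts['n_candidates']}",
        f"included segments (strict): {counts['n_included']}",
    ] + [f"  excluded [{k}]: {v}" for k, v in sorted(excl.items())]
    return {"counts": counts, "text": "\n".join(lines)}


def _load_cohort(config: PipelineConfig):
    if config.input_dir is None:
        sim = config.simulation
        sim.seed = config.seed
        return simulate_cohort(sim)
    by_subject: dict[str, list[WaveformRecord]] = defaultdict(list)
    paths = sorted(Path(config.input_dir).glob("*.csv")) + sorted(
        Path(config.input_dir).glob("*.hea")
    )
    for p in paths:
        rec = read_record(p, config.channel_roles)
        by_subject[rec.subject_id].append(rec)
    cohort = []
    for sid in sorted(by_subject):
        try:
            cohort.append((select_longest_record(by_subject[sid]), None))
        except IneligibleSubjectError as err:
            logger.info("subject %s excluded: %s", sid, err.reason)
    return cohort


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    cohort: list[tuple[WaveformRecord, SimulationTruth | None]] | None = None,
    make_figures: bool = True,
) -> PipelineResult:
    """Execute the full analysis and (optionally) write its artifacts."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    if cohort is None:
        cohort = _load_cohort(config)

    subjects = [analyze_record(rec, config, truth) for rec, truth in cohort]

    all_fits = [f for s in subjects for f in s.fits]
    summaries: dict = {}
    if all_fits:
        summaries = summarize_cohort(all_fits)

    ba = None
    pairs, r_pairs = [], []
    for s in subjects:
        if s.secondary_fit is None or not s.fits:
            continue
        prim = s.fits[0]
        if prim.degenerate or s.secondary_fit.degenerate:
            continue
        pairs.append((prim.slope, s.secondary_fit.slope))
        r_pairs.append((prim.pearson_r, s.secondary_fit.pearson_r))
    if len(pairs) >= 2:
        res = bland_altman(pairs, r_pairs)
        ba = {
            "mean_bias": res.mean_bias,
            "loa_low": res.loa_low,
            "loa_high": res.loa_high,
            "n_pairs": res.n_pairs,
            "sign_flip_fraction": res.sign_flip_fraction,
        }

    excl: dict[str, int] = defaultdict(int)
    n_candidates = n_included = 0
    for s in subjects:
        for seg in s.segments_strict:
            n_candidates += 1
            if seg.status == STATUS_EXCLUDED:
                excl[seg.exclusion_reason] += 1
            else:
                n_included += 1
    flow = report_inclusion_flow(
        {
            "n_subjects": len(subjects),
            "n_eligible": len(subjects),
            "n_with_candidates": sum(1 for s in subjects if s.candidates),
            "n_candidates": n_candidates,
            "n_included": n_included,
            "n_included_relaxed": sum(
                1
                for s in subjects
                for seg in s.segments_relaxed
                if seg.status != STATUS_EXCLUDED
            ),
            "exclusions": dict(sorted(excl.items())),
        }
    )

    result = PipelineResult(
        subjects=subjects,
        cohort_summaries=summaries,
        bland_altman=ba,
        inclusion_flow=flow,
        out_dir=Path(out_dir) if out_dir else None,
    )
    if out_dir is not None:
        _write_artifacts(result, config, Path(out_dir), make_figures)
    return result


def _write_artifacts(
    result: PipelineResult,
    config: PipelineConfig,
    out_dir: Path,
    make_figures: bool,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    strict = segments_to_frame(
        [seg for s in result.subjects for seg in s.segments_strict]
    )
    relaxed = segments_to_frame(
        [seg for s in result.subjects for seg in s.segments_relaxed]
    )
    fmt = "%.10g"
    strict.to_csv(out_dir / "events_strict.csv", index=False, float_format=fmt)
    relaxed.to_csv(out_dir / "events_relaxed.csv", index=False, float_format=fmt)
    fits = [f for s in result.subjects for f in s.fits] + [
        s.secondary_fit for s in result.subjects if s.secondary_fit is not None
    ]
    results_to_frame(fits).to_csv(
        out_dir / "regressions.csv", index=False, float_format=fmt
    )
    with open(out_dir / "cohort_summary.json", "w") as fh:
        json.dump(
            {
                "per_predictor": result.cohort_summaries,
                "bland_altman": result.bland_altman,
            },
            fh,
            indent=2,
            default=float,
        )
    with open(out_dir / "inclusion_flow.json", "w") as fh:
        json.dump(result.inclusion_flow["counts"], fh, indent=2)
    (out_dir / "inclusion_flow.txt").write_text(result.inclusion_flow["text"] + "\n")
    config.to_yaml(str(out_dir / "config_used.yaml"))
    if make_figures:
        from . import plots

        plots.make_all_figures(result, out_dir)
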