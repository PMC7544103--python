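"""Configuration objects for the simulator and the analysis pipeline.

Every analysis constant (hypotension thresholds, averaging width, ESQI cutoff,
peak-search windows) lives here with its default, so a whole run is
reproducible from one declarative config plus a seed.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration cannot describe a realizable record."""


@dataclass
class SimulationConfig:
    """Parameters of the paired ECG/ABP waveform simulator.

    The simulator renders, per subject, a beat train with respiratory sinus
    arrhythmia, a systolic-pressure trajectory containing ``n_events``
    hypotensive ramps (baseline -> nadir over ``ramp_duration`` seconds, a
    nadir hold, then recovery), a respiration-driven SBP oscillation offset in
    phase from the heart-rate oscillation, and a pulse transit time linearly
    coupled to SBP through a per-subject slope drawn from
    ``Normal(true_slope_mean, true_slope_sd)``.

    Units: pressures mmHg, times seconds unless suffixed, slopes mmHg/ms,
    rates per minute, ECG amplitudes in arbitrary millivolt-scale units.
    """

    n_subjects: int = 50
    fs: float = 125.0
    record_duration: float = 1500.0
    mean_hr: float = 85.0
    rsa_depth: float = 2.5            # RSA amplitude, beats/min
    resp_rate: float = 15.0           # breaths/min
    resp_bp_amp: float = 4.0          # respiratory SBP oscillation, mmHg
    resp_phase_offset: float = math.pi / 2.0  # HR-vs-BP oscillation offset, rad
    sbp_baseline: float = 125.0
    sbp_nadir: float = 85.0
    ramp_onset: float = 180.0
    ramp_duration: float = 300.0
    n_events: int = 2
    nadir_hold: float = 60.0
    recovery_duration: float = 180.0
    inter_event_gap: float = 120.0
    true_slope_mean: float = -1.23    # mmHg/ms
    true_slope_sd: float = 0.4
    ptt_at_baseline: float = 320.0    # ms, PTT when SBP == sbp_baseline
    sbp_noise_sd: float = 3.0
    ptt_noise_sd: float = 4.0
    ecg_noise_sd: float = 0.02
    abp_noise_sd: float = 0.5
    p_missing_beat: float = 0.001
    p_ambiguous_beat: float = 0.001
    hr_coupling: str = "independent"  # or "baroreflex"
    baroreflex_gain: float = 0.3      # beats/min per mmHg of SBP drop
    pulse_pressure: float = 45.0      # SBP - DBP of the rendered pulse
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for name in ("p_missing_beat", "p_ambiguous_beat"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.p_missing_beat + self.p_ambiguous_beat > 1.0:
            raise ConfigurationError("artifact probabilities sum above 1")
        if self.sbp_baseline <= self.sbp_nadir:
            raise ConfigurationError("sbp_baseline must exceed sbp_nadir")
        if self.ramp_duration > 900.0:
            raise ConfigurationError(
                "ramp_duration above 900 s cannot produce a qualifying event"
            )
        if self.hr_coupling not in ("independent", "baroreflex"):
            raise ConfigurationError("hr_coupling must be independent|baroreflex")
        if self.n_events < 1:
            raise ConfigurationError("n_events must be >= 1")
        if self.ramp_onset < 0:
            raise ConfigurationError("ramp_onset must be non-negative")
        if self.last_event_end + 10.0 > self.record_duration:
            raise ConfigurationError(
                "hypotensive events do not fit inside record_duration"
            )

    @property
    def event_cycle(self) -> float:
        """Seconds from one ramp onset to the next."""
        return (
            self.ramp_duration
            + self.nadir_hold
            + self.recovery_duration
            + self.inter_event_gap
        )

    @property
    def last_event_end(self) -> float:
        """Time at which the final recovery completes."""
        return (
            self.ramp_onset
            + (self.n_events - 1) * self.event_cycle
            + self.ramp_duration
            + self.nadir_hold
            + self.recovery_duration
        )

    def event_onsets(self) -> list[float]:
        return [
            self.ramp_onset + k * self.event_cycle for k in range(self.n_events)
        ]


@dataclass
class DetectionConfig:
    """Thresholds of the R-peak / ABP-peak detectors and the ECG quality index."""

    bandpass_low: float = 5.0         # Hz, QRS band
    bandpass_high: float = 15.0
    refractory: float = 0.2           # s, minimum spacing between R detections
    integration_window: float = 0.15  # s, moving-window integrator width
    w_min: float = 0.05               # s, ABP search window start after R
    w_max: float = 1.0                # s, ABP search window cap
    abp_prominence: float = 10.0      # mmHg, minimum systolic peak prominence
    ambiguity_ratio: float = 0.90     # secondary/dominant peak height ratio
    esqi_half_width: float = 0.060    # s, QRS window half width for ESQI


@dataclass
class AveragingConfig:
    """Savitzky-Golay beat-series smoother (linear fit over 21 beats)."""

    width: int = 21
    order: int = 1


@dataclass
class EventCriteria:
    """Hypotension-event definition and segment inclusion thresholds."""

    sbp_high: float = 120.0           # mmHg, averaged SBP a segment starts from
    sbp_low: float = 90.0             # mmHg, averaged SBP defining hypotension
    window_s: float = 900.0           # s, maximum decline duration
    min_beats: int = 21               # minimum segment length in heartbeats
    esqi_min: float = 0.9
    relaxed_max_missing: int = 5      # relaxed mode: < 5 missing/ambiguous


DEFAULT_CHANNEL_ROLES: dict[str, tuple[str, ...]] = {
    "ecg": ("ECG", "II", "MLII", "III", "I", "V", "AVR", "AVL", "AVF"),
    "abp": ("ABP", "ART", "AO", "BP"),
}


@dataclass
class PipelineConfig:
    """End-to-end run configuration: input source, thresholds, seed."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    averaging: AveragingConfig = field(default_factory=AveragingConfig)
    events: EventCriteria = field(default_factory=EventCriteria)
    channel_roles: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_CHANNEL_ROLES.items()}
    )
    input_dir: str | None = None      # None -> simulate a cohort instead
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["channel_roles"] = {k: list(v) for k, v in self.channel_roles.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        for name, sub in (
            ("simulation", SimulationConfig),
            ("detection", DetectionConfig),
            ("averaging", AveragingConfig),
            ("events", EventCriteria),
        ):
            if name in d:
                kwargs[name] = sub(**d.pop(name))
        if "channel_roles" in d:
            kwargs["channel_roles"] = {
                k: tuple(v) for k, v in d.pop("channel_roles").items()
            }
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
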