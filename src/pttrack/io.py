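"""Waveform record containers and readers/writers.

Two on-disk formats are supported:

* WFDB signal/header pairs (``<record>.hea`` + ``<record>.dat``, format 16),
  the layout used by public ICU waveform databases. Samples are stored as
  little-endian int16 with a per-channel gain; the reserved value -32768 marks
  an invalid (gap) sample and round-trips to NaN.
* A plain-text CSV fixture format with a ``time_s`` column followed by one
  column per channel, preceded by a single comment line carrying record
  metadata. Floats are written losslessly (``%.17g``) so CSV round-trips are
  exact.

Gaps are kept as NaN everywhere; they are never zero-filled, and downstream
beat extraction flags any beat whose search window touches a gap.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import DEFAULT_CHANNEL_ROLES

WFDB_INVALID = -32768


class IneligibleSubjectError(Exception):
    """A subject has no record usable for analysis."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class WaveformRecord:
    """Multi-channel sampled record (ECG + arterial pressure) at a common rate."""

    subject_id: str
    record_id: str
    fs: float
    channels: dict[str, np.ndarray]
    roles: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must share one length")

    @property
    def n_samples(self) -> int:
        if not self.channels:
            return 0
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def eligible(self) -> bool:
        """True when both an ECG and an ABP channel were resolved."""
        return "ecg" in self.roles and "abp" in self.roles

    def channel(self, role: str) -> np.ndarray:
        if role not in self.roles:
            raise KeyError(f"role {role!r} not resolved on record {self.record_id}")
        return self.channels[self.roles[role]]


def resolve_roles(
    channel_names: list[str],
    patterns: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, str]:
    """Map analysis roles ('ecg', 'abp') onto channel names.

    Matching is case-insensitive: a channel qualifies for a role if any
    configured pattern appears as a word-ish substring of its name. Patterns
    are tried in priority order; the first matching channel wins.
    """
    patterns = patterns or DEFAULT_CHANNEL_ROLES
    roles: dict[str, str] = {}
    for role, pats in patterns.items():
        for pat in pats:
            for name in channel_names:
                if name in roles.values():
                    continue
                if re.search(rf"(?<![A-Za-z]){re.escape(pat)}(?![A-Za-z])",
                             name, re.IGNORECASE) or name.upper() == pat.upper():
                    roles[role] = name
                    break
            if role in roles:
                break
    return roles


# ---------------------------------------------------------------------------
# CSV fixture format


def write_csv_record(record: WaveformRecord, path: str | Path) -> Path:
    path = Path(path)
    names = list(record.channels)
    t = np.arange(record.n_samples) / record.fs
    cols = [t] + [record.channels[n] for n in names]
    header = (
        f"# subject_id={record.subject_id} record_id={record.record_id} "
        f"fs={record.fs!r}\n" + ",".join(["time_s"] + names)
    )
    data = np.column_stack(cols)
    np.savetxt(path, data, fmt="%.17g", delimiter=",", header=header, comments="")
    return path


def read_csv_record(
    path: str | Path,
    channel_role_map: dict[str, tuple[str, ...]] | None = None,
) -> WaveformRecord:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        meta: dict[str, str] = {}
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            header = fh.readline().strip()
        else:
            header = first
        names = header.split(",")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if names[0] != "time_s":
        raise ValueError(f"{path}: first column must be time_s")
    names = names[1:]
    if "fs" in meta:
        fs = float(meta["fs"])
    else:
        dt = np.median(np.diff(data[:, 0]))
        fs = 1.0 / dt
    channels = {n: np.ascontiguousarray(data[:, i + 1]) for i, n in enumerate(names)}
    rec = WaveformRecord(
        subject_id=meta.get("subject_id", path.stem),
        record_id=meta.get("record_id", path.stem),
        fs=fs,
        channels=channels,
    )
    rec.roles = resolve_roles(list(channels), channel_role_map)
    return rec


# ---------------------------------------------------------------------------
# Minimal WFDB (header + format-16 signal file)


def _choose_gain(x: np.ndarray) -> float:
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        return 200.0
    peak = float(np.max(np.abs(finite)))
    if peak == 0.0:
        return 200.0
    # keep digital values comfortably inside int16 while preserving resolution
    g = 30000.0 / peak
    return float(np.clip(g, 1e-6, 32000.0))


def write_wfdb_record(
    record: WaveformRecord,
    directory: str | Path,
    gains: dict[str, float] | None = None,
) -> Path:
    """Write ``<record_id>.hea`` and ``<record_id>.dat`` (format 16)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = list(record.channels)
    gains = gains or {}
    digital = np.empty((record.n_samples, len(names)), dtype=np.int16)
    sig_lines = []
    for j, name in enumerate(names):
        x = record.channels[name]
        gain = float(gains.get(name) or _choose_gain(x))
        d = np.round(x * gain)
        d = np.where(np.isfinite(x), d, WFDB_INVALID)
        d = np.clip(d, -32767, 32767).astype(np.int16)
        d[~np.isfinite(x)] = WFDB_INVALID
        digital[:, j] = d
        checksum = int(np.int16(np.sum(d, dtype=np.int64) & 0xFFFF))
        init = int(d[0]) if len(d) else 0
        unit = record.units.get(name, "units")
        sig_lines.append(
            f"{record.record_id}.dat 16 {gain:.6g}(0)/{unit} 16 0 "
            f"{init} {checksum} 0 {name}"
        )
    hea = directory / f"{record.record_id}.hea"
    with open(hea, "w") as fh:
        fh.write(
            f"{record.record_id} {len(names)} {record.fs:g} {record.n_samples}\n"
        )
        fh.write("\n".join(sig_lines) + "\n")
        fh.write(f"# subject_id={record.subject_id}\n")
    digital.tofile(directory / f"{record.record_id}.dat")
    return hea


def read_wfdb_record(
    header_path: str | Path,
    channel_role_map: dict[str, tuple[str, ...]] | None = None,
) -> WaveformRecord:
    header_path = Path(header_path)
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip()
    ]
    meta = {}
    for ln in lines:
        if ln.startswith("#"):
            for token in ln[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    lines = [ln for ln in lines if not ln.startswith("#")]
    rec_tokens = lines[0].split()
    record_id, n_sig = rec_tokens[0], int(rec_tokens[1])
    fs = float(rec_tokens[2]) if len(rec_tokens) > 2 else 250.0
    n_samples = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    names, gains, baselines, dat_file = [], [], [], None
    for ln in lines[1 : 1 + n_sig]:
        tokens = ln.split()
        dat_file = tokens[0]
        fmt = tokens[1].split("x")[0]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB format {fmt!r} (only 16)")
        gain_tok = tokens[2]
        m = re.match(r"([-0-9.eE+]+)(?:\(([-0-9.eE+]+)\))?(?:/(\S+))?", gain_tok)
        gain = float(m.group(1)) if m and m.group(1) else 200.0
        baseline = float(m.group(2)) if m and m.group(2) else 0.0
        if gain == 0:
            gain = 200.0
        gains.append(gain)
        baselines.append(baseline)
        names.append(tokens[8] if len(tokens) > 8 else f"sig{len(names)}")
    raw = np.fromfile(header_path.with_name(dat_file), dtype="<i2")
    raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig)
    if n_samples:
        raw = raw[:n_samples]
    channels = {}
    for j, name in enumerate(names):
        d = raw[:, j].astype(float)
        x = (d - baselines[j]) / gains[j]
        x[raw[:, j] == WFDB_INVALID] = np.nan
        channels[name] = x
    rec = WaveformRecord(
        subject_id=meta.get("subject_id", record_id),
        record_id=record_id,
        fs=fs,
        channels=channels,
    )
    rec.roles = resolve_roles(names, channel_role_map)
    return rec


def read_record(
    path: str | Path,
    channel_role_map: dict[str, tuple[str, ...]] | None = None,
) -> WaveformRecord:
    """Read a record from either supported format, resolving channel roles.

    A record lacking an ECG or ABP channel is returned with the role missing
    and ``eligible == False`` rather than raising, so cohort scans can skip it
    silently.
    """
    path = Path(path)
    if path.suffix == ".hea":
        return read_wfdb_record(path, channel_role_map)
    if path.suffix == ".csv":
        return read_csv_record(path, channel_role_map)
    raise ValueError(f"unrecognized record format: {path}")


def select_longest_record(records: list[WaveformRecord]) -> WaveformRecord:
    """Pick the analysis record for a subject: the longest eligible one.

    Ties are broken by lexicographically smallest ``record_id`` so the choice
    is permutation-invariant. Raises :class:`IneligibleSubjectError` when no
    record has both channel roles.
    """
    if not records:
        raise ValueError("select_longest_record requires at least one record")
    eligible = [r for r in records if r.eligible]
    if not eligible:
        raise IneligibleSubjectError("no-eligible-record")
    return min(eligible, key=lambda r: (-r.n_samples, r.record_id))
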