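"""Canonical session data types and on-disk formats.

A session couples a behavioral event log (lever presses, head entries,
reward deliveries; seconds from session start) with an optional matrix of
single-cell fluorescence traces sampled at a fixed rate (10 Hz by default).

On-disk formats:

* Behavior log — long-form CSV with header ``time_s,event`` where event is
  one of ``press``, ``head_entry``, ``reward``; metadata as leading
  ``#key=value`` comment lines.
* Trace matrix — either delimited text (first column cell id, remaining
  columns samples; 6 significant digits) or HDF5 (datasets ``raw`` and
  ``cell_ids``, root attributes ``sampling_rate_hz`` and ``t0_s``).
  HDF5 is the lossless interchange format.

All times are seconds from session start (0-based) and all windows in the
package are half-open ``[a, b)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np

__all__ = [
    "ScheduleSpec",
    "BehaviorLog",
    "TraceMatrix",
    "SessionBundle",
    "ValidationReport",
    "read_behavior_log",
    "write_behavior_log",
    "read_trace_matrix",
    "write_trace_matrix",
    "validate_session",
]

_EVENT_TOKENS = ("press", "head_entry", "reward")

SCHEDULE_KINDS = ("FR1", "NTC-FR4", "TC-FR4", "unknown")


class BehaviorLogParseError(ValueError):
    """Malformed behavior-log file; message names the offending line."""


@dataclass(frozen=True)
class ScheduleSpec:
    """Reinforcement schedule.

    kind
        ``FR1`` (every press rewarded), ``NTC-FR4`` (every ``ratio``-th
        press rewarded, no time constraint) or ``TC-FR4`` (the most recent
        ``ratio`` presses must span at most ``time_limit_s``).
    ratio
        Presses required per reward (>= 1).
    time_limit_s
        Window for the last ``ratio`` presses; required (> 0) for TC-FR4,
        None otherwise.
    label_hz
        Nominal rate tag (1/2/4/8 Hz); for TC-FR4 equals
        ``ratio / time_limit_s``.
    """

    kind: str
    ratio: int = 1
    time_limit_s: Optional[float] = None
    label_hz: Optional[float] = None

    def __post_init__(self):
        if self.kind not in SCHEDULE_KINDS:
            raise ValueError(f"unknown schedule kind {self.kind!r}; expected one of {SCHEDULE_KINDS}")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.kind == "TC-FR4":
            if self.time_limit_s is None or self.time_limit_s <= 0:
                raise ValueError("TC-FR4 requires time_limit_s > 0")
            nominal = self.ratio / self.time_limit_s
            if self.label_hz is not None and not np.isclose(self.label_hz, nominal):
                raise ValueError(
                    f"label_hz {self.label_hz} inconsistent with ratio/time_limit_s = {nominal}"
                )
            if self.label_hz is None:
                object.__setattr__(self, "label_hz", nominal)


@dataclass
class BehaviorLog:
    """Timestamped press / head-entry / reward events for one session."""

    session_id: str
    presses: np.ndarray
    head_entries: np.ndarray
    rewards: np.ndarray
    schedule: ScheduleSpec
    duration_s: float

    def __post_init__(self):
        self.presses = np.asarray(self.presses, dtype=float)
        self.head_entries = np.asarray(self.head_entries, dtype=float)
        self.rewards = np.asarray(self.rewards, dtype=float)
        for name in ("presses", "head_entries", "rewards"):
            arr = getattr(self, name)
            if arr.size and np.any(np.diff(arr) < 0):
                raise ValueError(f"{name} must be ascending")

    def events_in_session(self) -> bool:
        for arr in (self.presses, self.head_entries, self.rewards):
            if arr.size and (arr[0] < 0 or arr[-1] > self.duration_s):
                return False
        return True


@dataclass
class TraceMatrix:
    """Cells x samples fluorescence, raw and (once computed) ΔF/F₀ in %."""

    cell_ids: list
    sampling_rate_hz: float
    raw: np.ndarray
    dff: Optional[np.ndarray] = None
    t0_s: float = 0.0

    def __post_init__(self):
        self.raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if not np.all(np.isfinite(self.raw)):
            raise ValueError("raw traces must be finite")
        if len(self.cell_ids) != self.raw.shape[0]:
            raise ValueError("cell_ids length must match number of rows in raw")
        if self.dff is not None:
            self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
            if self.dff.shape != self.raw.shape:
                raise ValueError("dff shape must match raw")

    @property
    def n_cells(self) -> int:
        return self.raw.shape[0]

    @property
    def n_samples(self) -> int:
        return self.raw.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Sample times on the session clock."""
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def time_to_sample(self, t: float) -> int:
        """Nearest sample at or before session time ``t`` (floor snapping)."""
        return int(np.floor((t - self.t0_s) * self.sampling_rate_hz))


@dataclass
class SessionBundle:
    log: BehaviorLog
    traces: Optional[TraceMatrix] = None
    meta: dict = field(default_factory=dict)


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff consistent
        return self.ok


# ---------------------------------------------------------------------------
# Behavior-log CSV
# ---------------------------------------------------------------------------

def _schedule_to_meta(s: ScheduleSpec) -> dict:
    meta = {"schedule_kind": s.kind, "schedule_ratio": str(s.ratio)}
    if s.time_limit_s is not None:
        meta["schedule_time_limit_s"] = repr(float(s.time_limit_s))
    if s.label_hz is not None:
        meta["schedule_label_hz"] = repr(float(s.label_hz))
    return meta


def _schedule_from_meta(meta: dict) -> ScheduleSpec:
    kind = meta.get("schedule_kind", "unknown")
    ratio = int(meta.get("schedule_ratio", 1))
    tl = meta.get("schedule_time_limit_s")
    lh = meta.get("schedule_label_hz")
    return ScheduleSpec(
        kind=kind,
        ratio=ratio,
        time_limit_s=float(tl) if tl is not None else None,
        label_hz=float(lh) if lh is not None else None,
    )


def read_behavior_log(path) -> BehaviorLog:
    """Read a behavior log from long-form CSV.

    Expected layout: optional ``#key=value`` metadata lines, a header row
    ``time_s,event``, then one row per event. Events are partitioned by
    type and stably sorted by time (input order preserved among ties).
    """
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, str]] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line.replace(" ", "") != "time_s,event":
                    raise BehaviorLogParseError(
                        f"{path}:{lineno}: expected header 'time_s,event', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise BehaviorLogParseError(f"{path}:{lineno}: malformed row {line!r}")
            t_str, event = parts[0].strip(), parts[1].strip()
            try:
                t = float(t_str)
            except ValueError as exc:
                raise BehaviorLogParseError(f"{path}:{lineno}: bad time {t_str!r}") from exc
            if event not in _EVENT_TOKENS:
                raise BehaviorLogParseError(
                    f"{path}:{lineno}: unknown event token {event!r}; expected one of {_EVENT_TOKENS}"
                )
            rows.append((t, event))
    by_type = {tok: [] for tok in _EVENT_TOKENS}
    # stable sort by time; ties keep input order
    for t, event in sorted(rows, key=lambda r: r[0]):
        by_type[event].append(t)
    duration = float(meta.get("duration_s", rows[-1][0] if rows else 0.0))
    return BehaviorLog(
        session_id=meta.get("session_id", path.stem),
        presses=np.array(by_type["press"]),
        head_entries=np.array(by_type["head_entry"]),
        rewards=np.array(by_type["reward"]),
        schedule=_schedule_from_meta(meta),
        duration_s=duration,
    )


def write_behavior_log(log: BehaviorLog, path) -> None:
    """Write a behavior log as long-form CSV readable by :func:`read_behavior_log`."""
    path = Path(path)
    meta = {"session_id": log.session_id, "duration_s": repr(float(log.duration_s))}
    meta.update(_schedule_to_meta(log.schedule))
    events = (
        [(t, "press") for t in log.presses]
        + [(t, "head_entry") for t in log.head_entries]
        + [(t, "reward") for t in log.rewards]
    )
    events.sort(key=lambda r: r[0])
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"#{key}={val}\n")
        fh.write("time_s,event\n")
        for t, event in events:
            fh.write(f"{float(t)!r},{event}\n")


# ---------------------------------------------------------------------------
# Trace matrix: delimited text and HDF5
# ---------------------------------------------------------------------------

def write_trace_matrix(tm: TraceMatrix, path) -> None:
    """Write traces to ``.h5``/``.hdf5`` (lossless) or delimited text.

    The text format stores 6 significant digits; HDF5 round-trips exactly.
    Only the raw matrix is serialized — ΔF/F₀ is recomputed downstream.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("raw", data=tm.raw)
            f.create_dataset(
                "cell_ids", data=np.array([str(c) for c in tm.cell_ids], dtype="S")
            )
            f.attrs["sampling_rate_hz"] = tm.sampling_rate_hz
            f.attrs["t0_s"] = tm.t0_s
    else:
        with open(path, "w") as fh:
            fh.write(f"#sampling_rate_hz={tm.sampling_rate_hz!r}\n")
            fh.write(f"#t0_s={tm.t0_s!r}\n")
            for cid, row in zip(tm.cell_ids, tm.raw):
                vals = ",".join(f"{v:.6g}" for v in row)
                fh.write(f"{cid},{vals}\n")


def read_trace_matrix(path) -> TraceMatrix:
    """Read traces written by :func:`write_trace_matrix`."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "sampling_rate_hz" not in f.attrs:
                raise ValueError(f"{path}: missing sampling_rate_hz attribute")
            raw = np.asarray(f["raw"])
            cell_ids = [c.decode() if isinstance(c, bytes) else str(c) for c in f["cell_ids"]]
            return TraceMatrix(
                cell_ids=cell_ids,
                sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
                raw=raw,
                t0_s=float(f.attrs.get("t0_s", 0.0)),
            )
    meta: dict = {}
    cell_ids: list = []
    rows: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
                continue
            parts = line.split(",")
            cell_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise ValueError(f"{path}:{lineno}: ragged row (expected {len(rows[0])} samples)")
    if "sampling_rate_hz" not in meta:
        raise ValueError(f"{path}: missing sampling_rate_hz metadata")
    return TraceMatrix(
        cell_ids=cell_ids,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        raw=np.array(rows, dtype=float),
        t0_s=float(meta.get("t0_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# Session validation
# ---------------------------------------------------------------------------

def validate_session(bundle: SessionBundle) -> ValidationReport:
    """Check internal consistency of a session; reports, never raises.

    Flags events outside ``[0, duration_s]``, rewards that schedule replay
    cannot reproduce, and behavior/trace clock mismatch (trace span must
    cover the session within one sample period).
    """
    from .sequences import replay_reward_rule  # deferred: avoids import cycle

    report = ValidationReport()
    log = bundle.log
    if not log.events_in_session():
        report.violations.append("events outside [0, duration_s]")
    if log.schedule.kind != "unknown" and log.rewards.size:
        expected = replay_reward_rule(log, log.schedule)
        if len(expected) != log.rewards.size or not np.allclose(expected, log.rewards):
            report.violations.append(
                f"rewards not reproducible by schedule replay "
                f"(found {log.rewards.size}, replay gives {len(expected)})"
            )
    tm = bundle.traces
    if tm is not None:
        period = 1.0 / tm.sampling_rate_hz
        t_start = tm.t0_s
        t_end = tm.t0_s + tm.n_samples / tm.sampling_rate_hz
        if t_start > period or t_end < log.duration_s - period:
            report.violations.append(
                f"trace span [{t_start:.3f}, {t_end:.3f}) does not cover session "
                f"[0, {log.duration_s:.3f}) within one sample period"
            )
    return report
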