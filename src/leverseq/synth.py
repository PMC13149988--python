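"""Seeded synthetic sessions: operant behavior plus calcium traces.

The generator emulates the structure of head-fixed/freely-moving operant
lever-press sessions with miniscope calcium imaging:

* Press trains organized in runs ("unit sequences") drawn from three latent
  kinematic classes — fast-confined, slow-confined, slow-elongated — with
  log-normal inter-press intervals per class, separated by inter-sequence
  gaps always longer than the 3 s segmentation pause, optionally ended with
  a head entry.
* Rewards placed exactly where the reinforcement schedule grants them, so
  logs are schedule-consistent by construction.
* GCaMP6f-like fluorescence traces for three cell archetypes: instant-onset
  (responds within ±0.5 s of run start), delayed-onset (latency coupled to
  run duration), and sequentially tiled pyramidal-like cells. Transients
  are double-exponential kernels on a drifting multiplicative baseline with
  additive Gaussian noise.

Every draw flows from one integer seed through independently spawned
per-component streams, so behavior and calcium are separately reproducible.
Latent truth (per-run class, per-cell archetype, emitted event times) is
returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .session_io import BehaviorLog, ScheduleSpec, TraceMatrix
from .sequences import replay_reward_rule

__all__ = [
    "ClassKinematics",
    "AgentParams",
    "CellSpec",
    "GroundTruth",
    "simulate_behavior",
    "simulate_calcium",
    "make_scenario",
    "SCENARIO_NAMES",
    "LATENT_CLASSES",
]

LATENT_CLASSES = ("fast_confined", "slow_confined", "slow_elongated")

CELL_ARCHETYPES = ("instant", "delayed", "tiled_pyr")


@dataclass(frozen=True)
class ClassKinematics:
    """Within-run kinematics for one latent sequence class.

    Inter-press intervals are log-normal with the given mean (s) and
    geometric dispersion; run length (press count) is drawn uniformly from
    the inclusive range.
    """

    ipi_mean_s: float
    ipi_sigma_log: float
    run_length_range: Tuple[int, int]

    def __post_init__(self):
        if self.ipi_mean_s <= 0:
            raise ValueError("ipi_mean_s must be > 0")
        lo, hi = self.run_length_range
        if not 1 <= lo <= hi:
            raise ValueError("run_length_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class AgentParams:
    """Behavioral generator parameters for one session."""

    n_seqs: int = 100
    class_mix: Tuple[float, float, float] = (0.46, 0.295, 0.245)
    kinematics: Dict[str, ClassKinematics] = field(
        default_factory=lambda: {
            "fast_confined": ClassKinematics(0.20, 0.25, (4, 6)),
            "slow_confined": ClassKinematics(0.55, 0.30, (3, 5)),
            "slow_elongated": ClassKinematics(1.00, 0.40, (6, 10)),
        }
    )
    inter_seq_gap_mean_s: float = 8.0
    inter_seq_gap_min_s: float = 3.5
    head_entry_prob: float = 0.7
    suppression: bool = False
    suppression_run_scale: float = 1.8
    suppression_ipi_scale: float = 1.6

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.inter_seq_gap_min_s <= 3.0:
            raise ValueError("inter_seq_gap_min_s must exceed the 3 s pause threshold")
        if self.n_seqs < 1:
            raise ValueError("n_seqs must be >= 1")


@dataclass(frozen=True)
class CellSpec:
    """One synthetic cell.

    archetype: instant | delayed | tiled_pyr. response_amp is the transient
    peak in ΔF/F₀ %; latency_base_s the mean event latency from run start;
    duration_coupling the slope of latency on run duration (delayed cells);
    reliability the per-run event probability; kernel time constants in s.
    """

    archetype: str
    response_amp: float = 20.0
    latency_base_s: float = 0.0
    duration_coupling: float = 0.0
    latency_jitter_s: float = 0.1
    reliability: float = 0.9
    rise_s: float = 0.1
    decay_s: float = 0.6
    noise_sd: float = 1.0
    baseline_drift: float = 0.05
    spont_rate_hz: float = 0.02
    #: optional per-latent-class multiplier on response_amp, keyed by
    #: LATENT_CLASSES names (e.g. stronger transients on fast runs)
    class_amp_scale: Optional[Dict[str, float]] = None

    def __post_init__(self):
        if self.archetype not in CELL_ARCHETYPES:
            raise ValueError(f"archetype must be one of {CELL_ARCHETYPES}")
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError("reliability must be in [0, 1]")
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("kernel time constants must be > 0")
        if self.archetype == "instant" and abs(self.latency_base_s) > 0.5:
            raise ValueError("instant archetype requires |latency_base_s| <= 0.5")


@dataclass
class GroundTruth:
    """Latent state behind a generated session."""

    seq_classes: List[str] = field(default_factory=list)
    seq_press_times: List[np.ndarray] = field(default_factory=list)
    seq_starts: np.ndarray = field(default_factory=lambda: np.array([]))
    seq_durations: np.ndarray = field(default_factory=lambda: np.array([]))
    cell_specs: List[CellSpec] = field(default_factory=list)
    event_times: List[List[np.ndarray]] = field(default_factory=list)  # [cell][seq]
    spont_event_times: List[np.ndarray] = field(default_factory=list)  # [cell]


def _spawn(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_behavior(
    schedule: ScheduleSpec, agent: AgentParams, seed: int
) -> Tuple[BehaviorLog, GroundTruth]:
    """Draw one session of press runs, head entries, and schedule rewards.

    Runs are drawn per latent class; rewards are inserted exactly where
    :func:`leverseq.sequences.replay_reward_rule` grants them, so the log
    is schedule-consistent by construction. Identical seeds give identical
    output.
    """
    if schedule.kind in ("NTC-FR4", "TC-FR4"):
        max_run = max(k.run_length_range[1] for k in agent.kinematics.values())
        if agent.suppression:
            max_run = int(round(max_run * agent.suppression_run_scale))
        if max_run < schedule.ratio:
            raise ValueError(
                f"infeasible params: max run length {max_run} can never satisfy "
                f"ratio {schedule.ratio}"
            )
    rng = _spawn(seed, 1)[0]
    gt = GroundTruth()
    presses: List[float] = []
    head_entries: List[float] = []
    t = float(rng.uniform(5.0, 15.0))
    classes = rng.choice(len(LATENT_CLASSES), size=agent.n_seqs, p=agent.class_mix)
    for cls_idx in classes:
        cls = LATENT_CLASSES[cls_idx]
        kin = agent.kinematics[cls]
        lo, hi = kin.run_length_range
        ipi_mean = kin.ipi_mean_s
        if agent.suppression:
            lo = max(1, int(round(lo * agent.suppression_run_scale)))
            hi = max(lo, int(round(hi * agent.suppression_run_scale)))
            ipi_mean *= agent.suppression_ipi_scale
        n_press = int(rng.integers(lo, hi + 1))
        # log-normal IPIs with arithmetic mean ipi_mean
        mu_log = np.log(ipi_mean) - kin.ipi_sigma_log**2 / 2
        ipis = rng.lognormal(mu_log, kin.ipi_sigma_log, size=max(0, n_press - 1))
        ipis = np.minimum(ipis, 2.9)  # keep within-run gaps below the pause threshold
        run = t + np.concatenate([[0.0], np.cumsum(ipis)])
        presses.extend(run.tolist())
        gt.seq_classes.append(cls)
        gt.seq_press_times.append(run)
        gap = max(agent.inter_seq_gap_min_s, float(rng.exponential(agent.inter_seq_gap_mean_s)))
        if rng.random() < agent.head_entry_prob:
            head_entries.append(float(run[-1] + rng.uniform(0.3, min(2.5, gap - 0.2))))
        t = float(run[-1] + gap)
    duration = float(t + 5.0)
    gt.seq_starts = np.array([r[0] for r in gt.seq_press_times])
    gt.seq_durations = np.array([r[-1] - r[0] for r in gt.seq_press_times])
    log = BehaviorLog(
        session_id=f"synth-{schedule.kind}-{seed}",
        presses=np.array(presses),
        head_entries=np.array(sorted(head_entries)),
        rewards=np.array([]),
        schedule=schedule,
        duration_s=duration,
    )
    if schedule.kind != "unknown":
        log.rewards = replay_reward_rule(log, schedule)
    return log, gt


def _transient_kernel(rise_s: float, decay_s: float, rate_hz: float) -> Tuple[np.ndarray, float]:
    """Unit-peak double-exponential kernel and its peak offset (s)."""
    t_peak = rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s) if decay_s != rise_s else rise_s
    t = np.arange(0, t_peak + 6 * decay_s, 1.0 / rate_hz)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    k /= k.max()
    return k, float(t[np.argmax(k)])


def simulate_calcium(
    log: BehaviorLog,
    gt: GroundTruth,
    cells: Sequence[CellSpec],
    sampling_rate_hz: float = 10.0,
    seed: int = 0,
) -> Tuple[TraceMatrix, GroundTruth]:
    """Generate fluorescence traces locked to the session's press runs.

    Per cell: raw = baseline * drift * (1 + (signal + noise)/100), where
    signal is the ΔF/F₀-% sum of transients. Event placement per run:

    * instant — latency_base + jitter around run start;
    * delayed — latency_base + duration_coupling * run duration + jitter;
    * tiled_pyr — latency at a cell-specific fraction of the run duration
      (cells tile the sequence).

    Poisson background transients at ``spont_rate_hz`` occur anywhere.
    Ground truth gains every emitted event time.
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be > 0")
    n_samples = int(np.ceil(log.duration_s * sampling_rate_hz))
    t_axis = np.arange(n_samples) / sampling_rate_hz
    streams = _spawn(seed, len(cells))
    n_tiled = max(1, sum(c.archetype == "tiled_pyr" for c in cells))
    tiled_rank = 0
    raws = []
    gt.cell_specs = list(cells)
    gt.event_times = []
    gt.spont_event_times = []
    baseline = 100.0  # arbitrary fluorescence units
    for ci, (cell, rng) in enumerate(zip(cells, streams)):
        kernel, _ = _transient_kernel(cell.rise_s, cell.decay_s, sampling_rate_hz)
        signal = np.zeros(n_samples)
        per_seq_events: List[np.ndarray] = []
        if cell.archetype == "tiled_pyr":
            frac = (tiled_rank + 0.5) / n_tiled
            tiled_rank += 1
        for start, dur, seq_cls in zip(gt.seq_starts, gt.seq_durations, gt.seq_classes):
            if rng.random() >= cell.reliability:
                per_seq_events.append(np.array([]))
                continue
            amp = cell.response_amp
            if cell.class_amp_scale is not None:
                amp *= cell.class_amp_scale.get(seq_cls, 1.0)
            if cell.archetype == "instant":
                lat = cell.latency_base_s + rng.normal(0, cell.latency_jitter_s)
            elif cell.archetype == "delayed":
                lat = (
                    cell.latency_base_s
                    + cell.duration_coupling * dur
                    + rng.normal(0, cell.latency_jitter_s)
                )
            else:  # tiled_pyr
                lat = frac * dur + rng.normal(0, cell.latency_jitter_s)
            ev = start + lat
            per_seq_events.append(np.array([ev]))
            idx = int(round(ev * sampling_rate_hz))
            if 0 <= idx < n_samples:
                seg = min(len(kernel), n_samples - idx)
                signal[idx : idx + seg] += amp * kernel[:seg]
        n_spont = rng.poisson(cell.spont_rate_hz * log.duration_s)
        spont = np.sort(rng.uniform(0, log.duration_s, size=n_spont))
        for ev in spont:
            idx = int(round(ev * sampling_rate_hz))
            if 0 <= idx < n_samples:
                seg = min(len(kernel), n_samples - idx)
                signal[idx : idx + seg] += cell.response_amp * kernel[:seg]
        gt.event_times.append(per_seq_events)
        gt.spont_event_times.append(spont)
        drift = 1.0 + cell.baseline_drift * np.sin(2 * np.pi * t_axis / max(t_axis[-1], 1.0))
        noise = rng.normal(0, cell.noise_sd, size=n_samples) if cell.noise_sd > 0 else 0.0
        raws.append(baseline * drift * (1.0 + (signal + noise) / 100.0))
    tm = TraceMatrix(
        cell_ids=[f"cell{ci:03d}" for ci in range(len(cells))],
        sampling_rate_hz=sampling_rate_hz,
        raw=np.array(raws) if raws else np.zeros((0, n_samples)),
        t0_s=0.0,
    )
    return tm, gt


SCENARIO_NAMES = (
    "fr1_early",
    "fr1_late",
    "ntc_fr4",
    "tc_fr4_4hz",
    "tc_fr4_8hz",
    "tc_fr4_4hz_suppressed",
)


def _default_cells(instant_amp: float = 25.0, instant_rel: float = 0.9) -> List[CellSpec]:
    cells = [
        CellSpec("instant", response_amp=instant_amp, latency_base_s=0.05, reliability=instant_rel),
        CellSpec("instant", response_amp=instant_amp * 0.8, latency_base_s=-0.1, reliability=instant_rel),
        CellSpec("delayed", response_amp=20.0, latency_base_s=0.8, duration_coupling=0.5, reliability=0.9),
        CellSpec("delayed", response_amp=18.0, latency_base_s=1.2, duration_coupling=0.5, reliability=0.9),
    ]
    cells += [CellSpec("tiled_pyr", response_amp=15.0, reliability=0.8) for _ in range(4)]
    return cells


def make_scenario(name: str) -> Tuple[ScheduleSpec, AgentParams, List[CellSpec]]:
    """Documented presets covering the training stages of the task.

    ``fr1_early``/``fr1_late`` share the FR1 schedule; the late preset has
    attenuated instant-cell amplitude and reliability (training-stage
    attenuation of the action-locked response). ``tc_fr4_4hz_suppressed``
    is the interneuron-inactivation phenotype: longer runs, slower presses.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}")
    agent = AgentParams()
    if name == "fr1_early":
        return ScheduleSpec("FR1"), agent, _default_cells(instant_amp=25.0, instant_rel=0.9)
    if name == "fr1_late":
        return ScheduleSpec("FR1"), agent, _default_cells(instant_amp=12.0, instant_rel=0.6)
    if name == "ntc_fr4":
        return ScheduleSpec("NTC-FR4", ratio=4), agent, _default_cells()
    if name == "tc_fr4_4hz":
        return ScheduleSpec("TC-FR4", ratio=4, time_limit_s=1.0), agent, _default_cells()
    if name == "tc_fr4_8hz":
        return ScheduleSpec("TC-FR4", ratio=4, time_limit_s=0.5), agent, _default_cells()
    # tc_fr4_4hz_suppressed
    return (
        ScheduleSpec("TC-FR4", ratio=4, time_limit_s=1.0),
        replace(agent, suppression=True),
        _default_cells(),
    )
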