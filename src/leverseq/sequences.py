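"""Unit-sequence (SEQ) segmentation, kinematics and labels.

A unit sequence is a run of consecutive lever presses terminated by a head
entry, a pause longer than the pause threshold (3 s by default), or the end
of the session. Each sequence carries kinematic parameters (press count,
duration, press frequency, inter-sequence interval), reward status, a
kinematic class (C1/C2/C3, assigned by clustering), a complete/incomplete
label, and a short/long duration band.

Conventions adopted here:

* ``frequency_hz = (n_presses - 1) / duration_s`` for n >= 2 — the rate of
  inter-press events, which makes "4 presses within 1 s" correspond to
  >= 3 Hz under a 4 Hz schedule target. Single-press sequences carry NaN
  and are excluded from frequency-based statistics.
* Under TC-FR4, after each reward the press window restarts: presses that
  contributed to a reward do not count toward the next one.
* "Pause longer than 3 s" is measured press-to-press; the 3.0 s boundary
  itself does NOT split (strictly greater).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .session_io import BehaviorLog, ScheduleSpec

__all__ = [
    "SequenceTrial",
    "segment_sequences",
    "compute_kinematics",
    "replay_reward_rule",
    "label_complete_incomplete",
    "split_by_duration_quantiles",
    "DEFAULT_PAUSE_THRESHOLD_S",
    "COMPLETE_FREQ_HZ",
]

DEFAULT_PAUSE_THRESHOLD_S = 3.0
#: minimum press frequency for a "complete" sequence (strict >)
COMPLETE_FREQ_HZ = 4.0


@dataclass
class SequenceTrial:
    """One segmented press run with kinematics and labels."""

    seq_id: int
    press_times: np.ndarray
    terminated_by: str  # head_entry | pause | session_end
    termination_time_s: float  # boundary closing the trial window
    rewarded: bool = False
    inter_seq_interval_s: Optional[float] = None
    duration_s: float = float("nan")
    frequency_hz: float = float("nan")
    class_label: str = "unassigned"  # C1 | C2 | C3 | unassigned
    completeness: str = "neither"  # complete | incomplete | neither
    duration_band: str = "middle"  # short | long | middle
    efficiency: Optional[float] = None

    def __post_init__(self):
        self.press_times = np.asarray(self.press_times, dtype=float)
        if self.press_times.size == 0:
            raise ValueError("a sequence trial needs at least one press")

    @property
    def start_s(self) -> float:
        return float(self.press_times[0])

    @property
    def end_s(self) -> float:
        return float(self.press_times[-1])

    @property
    def n_presses(self) -> int:
        return int(self.press_times.size)


def segment_sequences(
    log: BehaviorLog, pause_threshold_s: float = DEFAULT_PAUSE_THRESHOLD_S
) -> List[SequenceTrial]:
    """Partition the press train into unit sequences.

    A sequence ends at press ``p`` when the next press comes more than
    ``pause_threshold_s`` later, when a head entry falls strictly between
    ``p`` and the next press, or when the session ends. Every press belongs
    to exactly one sequence; kinematics, inter-sequence intervals and
    reward status are filled in.
    """
    presses = np.asarray(log.presses, dtype=float)
    if presses.size == 0:
        return []
    entries = np.asarray(log.head_entries, dtype=float)
    rewards = np.asarray(log.rewards, dtype=float)

    trials: List[SequenceTrial] = []
    run_start = 0
    for i in range(presses.size):
        last_press = i == presses.size - 1
        if last_press:
            boundary = True
            next_press = log.duration_s
        else:
            next_press = presses[i + 1]
            boundary = next_press - presses[i] > pause_threshold_s
        # head entry strictly inside the gap terminates the run regardless
        lo, hi = presses[i], next_press
        gap_entries = entries[(entries > lo) & (entries < hi)]
        if gap_entries.size:
            terminated_by = "head_entry"
            termination_time = float(gap_entries[0])
            boundary = True
        elif last_press:
            if log.duration_s - presses[i] > pause_threshold_s:
                terminated_by = "pause"
                termination_time = float(min(presses[i] + pause_threshold_s, log.duration_s))
            else:
                terminated_by = "session_end"
                termination_time = float(log.duration_s)
        elif boundary:
            terminated_by = "pause"
            termination_time = float(next_press)
        if boundary:
            run = presses[run_start : i + 1]
            trial = SequenceTrial(
                seq_id=len(trials),
                press_times=run,
                terminated_by=terminated_by,
                termination_time_s=termination_time,
            )
            trial.rewarded = bool(
                np.any((rewards >= trial.start_s) & (rewards < termination_time))
                or np.any(rewards == trial.end_s)
            )
            compute_kinematics(trial)
            trials.append(trial)
            run_start = i + 1
    for prev, cur in zip(trials, trials[1:]):
        cur.inter_seq_interval_s = cur.start_s - prev.end_s
    return trials


def compute_kinematics(seq: SequenceTrial) -> SequenceTrial:
    """Fill duration and press frequency.

    Frequency is ``(n - 1) / duration`` for n >= 2; a single-press trial
    gets duration 0 and NaN frequency (excluded from rate statistics).
    """
    seq.duration_s = seq.end_s - seq.start_s
    if seq.n_presses >= 2 and seq.duration_s > 0:
        seq.frequency_hz = (seq.n_presses - 1) / seq.duration_s
    else:
        seq.frequency_hz = float("nan")
    return seq


def replay_reward_rule(log: BehaviorLog, schedule: ScheduleSpec) -> np.ndarray:
    """Reward times the schedule would have delivered for this press train.

    FR1 rewards every press. NTC-FR4 rewards every ``ratio``-th press since
    the last reward. TC-FR4 rewards press ``k`` when the most recent
    ``ratio`` presses since the last reward span at most ``time_limit_s``;
    after a reward the window restarts.
    """
    presses = np.asarray(log.presses, dtype=float)
    if schedule.kind == "FR1":
        return presses.copy()
    if schedule.kind == "NTC-FR4":
        if presses.size < schedule.ratio:
            return np.array([])
        return presses[schedule.ratio - 1 :: schedule.ratio].copy()
    if schedule.kind == "TC-FR4":
        rewards = []
        window: list[float] = []  # presses since last reward
        for t in presses:
            window.append(t)
            if len(window) >= schedule.ratio and (
                window[-1] - window[-schedule.ratio] <= schedule.time_limit_s
            ):
                rewards.append(t)
                window.clear()
        return np.array(rewards)
    raise ValueError(f"unknown schedule kind {schedule.kind!r}")


def label_complete_incomplete(
    seqs: Sequence[SequenceTrial], freq_threshold_hz: float = COMPLETE_FREQ_HZ
) -> List[SequenceTrial]:
    """Assign complete/incomplete labels from class, rate and reward.

    Complete: class C1, frequency strictly above ``freq_threshold_hz``, and
    rewarded. Incomplete: class C3 and not rewarded. Everything else is
    "neither". Requires class labels — run clustering first.
    """
    for seq in seqs:
        if seq.class_label == "unassigned":
            raise ValueError(
                f"seq {seq.seq_id} has no class label; run kinematic clustering "
                "(seq_clustering) before complete/incomplete labeling"
            )
        if (
            seq.class_label == "C1"
            and seq.rewarded
            and not math.isnan(seq.frequency_hz)
            and seq.frequency_hz > freq_threshold_hz
        ):
            seq.completeness = "complete"
        elif seq.class_label == "C3" and not seq.rewarded:
            seq.completeness = "incomplete"
        else:
            seq.completeness = "neither"
    return list(seqs)


def split_by_duration_quantiles(
    seqs: Sequence[SequenceTrial], q: float = 0.30
) -> List[SequenceTrial]:
    """Label the shortest/longest duration fractions as short/long bands.

    The lowest ``q`` fraction of the duration distribution is "short", the
    highest ``q`` fraction "long", the rest "middle". Ranks use a stable
    sort so ties are resolved by input order; bands are disjoint — if the
    two cut values collide (e.g. all durations equal) everything is
    "middle".
    """
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    n = len(seqs)
    if n < math.ceil(1.0 / q):
        raise ValueError(f"need at least {math.ceil(1.0 / q)} sequences for q={q}")
    durations = np.array([s.duration_s for s in seqs])
    k = int(round(q * n))
    order = np.argsort(durations, kind="stable")
    sorted_d = durations[order]
    for s in seqs:
        s.duration_band = "middle"
    if k == 0 or sorted_d[k - 1] >= sorted_d[n - k]:
        return list(seqs)  # quantiles collide: middle wins
    for idx in order[:k]:
        seqs[idx].duration_band = "short"
    for idx in order[n - k :]:
        seqs[idx].duration_band = "long"
    return list(seqs)
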