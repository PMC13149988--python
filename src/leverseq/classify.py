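"""Onset-latency cell classification and trial-level associations.

Cells are classified from their trial-averaged response aligned to
sequence initiation: a cell whose dominant peak (global maximum of the
average curve within [-0.5, 5] s) falls within ±0.5 s of initiation is
"instant-onset"; one whose peak falls in (0.5, 5] s is "delayed-onset".
Cells whose peak does not clear a circular-shuffle baseline band (or falls
outside both windows) are "unclassified". The three groups partition the
population.

Trial-level statistics quantify how single-trial activity tracks sequence
structure: peak-latency vs sequence-duration regression (with Spearman rank
correlation) and efficiency vs session-normalized peak regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .calcium import AlignedResponse, EventTrain, align_responses
from .session_io import TraceMatrix
from .sequences import SequenceTrial

__all__ = [
    "OnsetClass",
    "AssociationResult",
    "classify_onset",
    "shuffle_baseline",
    "trial_peak_latency",
    "duration_latency_association",
    "efficiency_activity_association",
    "session_normalized_trial_peaks",
    "INSTANT_WINDOW_S",
    "DELAYED_WINDOW_S",
]

#: dominant-peak window for instant-onset cells, inclusive both ends (s)
INSTANT_WINDOW_S = (-0.5, 0.5)
#: dominant-peak window for delayed-onset cells, half-open low end (s)
DELAYED_WINDOW_S = (0.5, 5.0)


@dataclass
class OnsetClass:
    cell_ids: list
    labels: List[str]  # instant | delayed | unclassified
    peak_latency_s: np.ndarray
    peak_value: np.ndarray
    significant: np.ndarray  # peak exceeds shuffle band (all True if gate off)


@dataclass
class AssociationResult:
    """OLS fit plus Spearman rank correlation for paired trial data."""

    slope: float
    intercept: float
    r_squared: float
    slope_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    slope_stderr: float = float("nan")

    def slope_ci(self, level: float = 0.95) -> Tuple[float, float]:
        half = stats.t.ppf(0.5 + level / 2, self.n - 2) * self.slope_stderr
        return self.slope - half, self.slope + half


def _shuffle_curves(
    tm: TraceMatrix,
    anchors: np.ndarray,
    n_shuffles: int,
    seed: int,
    pre_s: float,
    post_s: float,
) -> np.ndarray:
    """Null trial-averaged curves (shuffles x cells x bins) from circular
    anchor shifts."""
    rng = np.random.default_rng(seed)
    span = tm.n_samples / tm.sampling_rate_hz
    curves = []
    for _ in range(n_shuffles):
        offset = rng.uniform(0, span)
        shifted = tm.t0_s + (anchors - tm.t0_s + offset) % span
        aligned = align_responses(tm, shifted, pre_s=pre_s, post_s=post_s)
        if aligned.tensor.shape[0] == 0:
            continue
        curves.append(aligned.mean_curves())
    return np.stack(curves)


def shuffle_baseline(
    tm: TraceMatrix,
    anchors: Sequence[float],
    n_shuffles: int = 200,
    seed: int = 0,
    pre_s: float = 5.0,
    post_s: float = 5.0,
    band: float = 0.95,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Null peri-event curves from circularly shifted anchors.

    Each shuffle shifts all anchors by one uniform offset modulo the trace
    span and recomputes the trial-averaged curve. Returns (null mean,
    lower band, upper band), each cells x bins, where the band is the
    central ``band`` fraction of the shuffle distribution. Seeded and
    deterministic.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 for a stable band")
    anchors = np.asarray(anchors, dtype=float)
    stack = _shuffle_curves(tm, anchors, n_shuffles, seed, pre_s, post_s)
    lo = np.percentile(stack, 100 * (0.5 - band / 2), axis=0)
    hi = np.percentile(stack, 100 * (0.5 + band / 2), axis=0)
    return stack.mean(axis=0), lo, hi


def classify_onset(
    tm: TraceMatrix,
    seq_anchors: Sequence[float],
    pre_s: float = 5.0,
    post_s: float = 5.0,
    shuffle_gate: bool = True,
    n_shuffles: int = 200,
    seed: int = 0,
) -> OnsetClass:
    """Partition cells into instant / delayed / unclassified onset groups.

    The dominant peak is the global maximum of the trial-averaged curve
    within [-0.5, 5] s of sequence initiation; ties break toward the
    earlier latency (argmax convention). With ``shuffle_gate`` on, the peak
    must also exceed the 95th percentile of the per-shuffle maxima over the
    same window (a max-statistic correction — a pointwise band would flag
    the maximum of a null curve far too often).
    """
    aligned = align_responses(tm, seq_anchors, pre_s=pre_s, post_s=post_s)
    if aligned.tensor.shape[0] == 0:
        raise ValueError("no alignable trials")
    curves = aligned.mean_curves()
    bt = aligned.bin_times
    search = (bt >= INSTANT_WINDOW_S[0]) & (bt <= DELAYED_WINDOW_S[1])
    sub = curves[:, search]
    sub_t = bt[search]
    peak_idx = np.argmax(sub, axis=1)  # first max -> earlier latency on ties
    peak_val = sub[np.arange(sub.shape[0]), peak_idx]
    peak_lat = sub_t[peak_idx]

    if shuffle_gate:
        if n_shuffles < 100:
            raise ValueError("n_shuffles must be >= 100 for a stable gate")
        stack = _shuffle_curves(
            tm, np.asarray(seq_anchors, dtype=float), n_shuffles, seed, pre_s, post_s
        )
        null_max = stack[:, :, search].max(axis=2)  # shuffles x cells
        significant = peak_val > np.percentile(null_max, 95, axis=0)
    else:
        significant = np.ones(sub.shape[0], dtype=bool)

    labels = []
    for lat, sig in zip(peak_lat, significant):
        if not sig:
            labels.append("unclassified")
        elif INSTANT_WINDOW_S[0] <= lat <= INSTANT_WINDOW_S[1]:
            labels.append("instant")
        elif DELAYED_WINDOW_S[0] < lat <= DELAYED_WINDOW_S[1]:
            labels.append("delayed")
        else:
            labels.append("unclassified")
    return OnsetClass(
        cell_ids=list(tm.cell_ids),
        labels=labels,
        peak_latency_s=peak_lat,
        peak_value=peak_val,
        significant=significant,
    )


def trial_peak_latency(
    tm: TraceMatrix,
    events: EventTrain,
    seq: SequenceTrial,
    cell_index: int,
    search_window_s: Tuple[float, float] = DELAYED_WINDOW_S,
) -> Optional[float]:
    """Latency of the strongest detected event after sequence initiation.

    Searches the half-open-at-the-left window ``(lo, hi]`` after the first
    press; returns the latency of the largest-amplitude detected event, or
    None when no event falls in the window.
    """
    lo, hi = search_window_s
    t = events.times[cell_index]
    a = events.amplitudes[cell_index]
    rel = t - seq.start_s
    mask = (rel > lo) & (rel <= hi)
    if not mask.any():
        return None
    return float(rel[mask][np.argmax(a[mask])])


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, float, float]:
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2, res.pvalue, res.stderr


def duration_latency_association(
    latencies: Sequence[Optional[float]], durations: Sequence[float]
) -> AssociationResult:
    """Regress single-trial peak latency on sequence duration.

    Pairs with absent latencies are dropped; needs >= 3 remaining pairs.
    Returns the OLS fit plus two-tailed Spearman rank correlation.
    """
    pairs = [(d, l) for d, l in zip(durations, latencies) if l is not None and np.isfinite(d)]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 paired observations, have {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.all(x == x[0]):
        raise ValueError("degenerate design: duration has no variance")
    slope, intercept, r2, p, se = _ols(x, y)
    rho, rho_p = stats.spearmanr(x, y)
    return AssociationResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        slope_p=p,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        n=len(pairs),
        slope_stderr=se,
    )


def efficiency_activity_association(
    efficiencies: Sequence[float], normalized_peaks: Sequence[float]
) -> AssociationResult:
    """Regress per-trial population activity on sequence efficiency.

    ``normalized_peaks`` is one value per sequence: the population-mean
    peak ΔF/F₀ normalized within the session (per-cell division by the
    session-wide maximum of the trial response, then averaged over cells).
    """
    x = np.asarray(efficiencies, dtype=float)
    y = np.asarray(normalized_peaks, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired observations, have {x.size}")
    if np.all(x == x[0]):
        raise ValueError("degenerate design: efficiency has no variance")
    slope, intercept, r2, p, se = _ols(x, y)
    rho, rho_p = stats.spearmanr(x, y)
    return AssociationResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        slope_p=p,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        n=int(x.size),
        slope_stderr=se,
    )


def session_normalized_trial_peaks(
    tm: TraceMatrix, seq_anchors: Sequence[float], pre_s: float = 1.0, post_s: float = 5.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-trial population activity, session-normalized.

    For each cell, the single-trial peak ΔF/F₀ in the peri-initiation
    window is divided by that cell's maximum trial peak across the session;
    the population value is the mean over cells. Returns (values, anchors
    actually used) — edge-clipped anchors are dropped by the alignment.
    """
    aligned = align_responses(tm, seq_anchors, pre_s=pre_s, post_s=post_s)
    if aligned.tensor.shape[0] == 0:
        raise ValueError("no alignable trials")
    trial_peaks = aligned.tensor.max(axis=2)  # trials x cells
    cell_max = trial_peaks.max(axis=0)
    cell_max[cell_max == 0] = 1.0
    return (trial_peaks / cell_max).mean(axis=1), aligned.anchors
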