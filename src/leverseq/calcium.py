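"""Trace-level calcium computations.

ΔF/F₀ extraction, discrete transient (event) detection, peri-event
alignment, event-probability curves, action-locked peak statistics
normalized to spontaneous activity, and pairwise-correlation population
synchrony.

Anchor snapping is floor-to-sample and every window is half-open
``[anchor - pre, anchor + post)``. ΔF/F₀ is expressed in percent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import percentile_filter, uniform_filter1d
from scipy.signal import find_peaks

from .session_io import TraceMatrix

__all__ = [
    "EventTrain",
    "AlignedResponse",
    "PethSummary",
    "compute_dff",
    "detect_events",
    "align_responses",
    "event_probability",
    "spontaneous_epochs",
    "action_locked_peak",
    "pairwise_correlation",
]

logger = logging.getLogger(__name__)

#: default prominence threshold in robust-noise (MAD) units
DEFAULT_MIN_PROMINENCE = 3.5
#: default minimum separation between detected events (s)
DEFAULT_MIN_SEPARATION_S = 0.3


@dataclass
class EventTrain:
    """Detected calcium transients: per cell, ascending times (s) and peak
    amplitudes (ΔF/F₀ %)."""

    cell_ids: list
    times: List[np.ndarray]
    amplitudes: List[np.ndarray]

    def n_events(self) -> np.ndarray:
        return np.array([t.size for t in self.times])


@dataclass
class AlignedResponse:
    """Per-trial, per-cell peri-event tensor over a fixed window."""

    tensor: np.ndarray  # trials x cells x bins
    anchors: np.ndarray  # alignment times actually used (s)
    pre_s: float
    post_s: float
    bin_s: float

    @property
    def bin_times(self) -> np.ndarray:
        """Bin start times relative to the anchor."""
        n_bins = self.tensor.shape[2]
        return -self.pre_s + np.arange(n_bins) * self.bin_s

    def mean_curves(self) -> np.ndarray:
        """Trial-averaged response per cell (cells x bins)."""
        return self.tensor.mean(axis=0)


@dataclass
class PethSummary:
    """Per-cell peri-event summary with spontaneous normalization."""

    cell_ids: list
    mean_curves: np.ndarray  # cells x bins
    bin_times: np.ndarray
    peak_value: np.ndarray
    peak_latency_s: np.ndarray
    spontaneous_peak: np.ndarray
    normalized_peak: np.ndarray


def compute_dff(
    tm: TraceMatrix,
    method: str = "percentile",
    percentile: float = 10.0,
    window_s: float = 60.0,
    poly_order: int = 3,
) -> TraceMatrix:
    """Compute ΔF/F₀ = 100 * (F - F₀) / F₀ per cell (in place, returned).

    Baseline methods:

    * ``"percentile"`` (default) — running low-percentile filter over a
      ``window_s`` sliding window, then smoothed with a boxcar of the same
      width. Tracks slow drift while ignoring transients.
    * ``"poly"`` — low-order polynomial fit to sub-threshold samples
      (those below the trace median plus one robust SD), iterated once.

    Raises if the fitted baseline is not strictly positive anywhere.
    """
    F = tm.raw
    win = max(3, int(round(window_s * tm.sampling_rate_hz)))
    win = min(win, F.shape[1])
    F0 = np.empty_like(F)
    for i in range(F.shape[0]):
        if method == "percentile":
            base = percentile_filter(F[i], percentile, size=win, mode="nearest")
            base = uniform_filter1d(base, size=win, mode="nearest")
        elif method == "poly":
            x = np.arange(F.shape[1])
            resid = F[i] - np.median(F[i])
            mad = np.median(np.abs(resid - np.median(resid))) * 1.4826
            mask = F[i] <= np.median(F[i]) + mad
            if mask.sum() < poly_order + 1:
                mask[:] = True
            coef = np.polyfit(x[mask], F[i][mask], poly_order)
            base = np.polyval(coef, x)
        else:
            raise ValueError(f"unknown baseline method {method!r}")
        if np.any(base <= 0):
            raise ValueError(f"non-positive baseline F0 for cell {tm.cell_ids[i]!r}")
        F0[i] = base
    tm.dff = 100.0 * (F - F0) / F0
    return tm


def _robust_noise_sd(x: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * median absolute deviation."""
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def detect_events(
    tm: TraceMatrix,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> EventTrain:
    """Detect discrete calcium transients as prominent local ΔF/F₀ maxima.

    A peak qualifies when both its height and its local prominence
    (measured within a ±5 s neighborhood) reach ``min_prominence``
    robust-noise units (MAD-based), and it is separated from larger peaks
    by at least ``min_separation_s``. Deterministic; a flat trace yields an
    empty train.
    """
    if tm.dff is None:
        raise ValueError("compute_dff first")
    distance = max(1, int(round(min_separation_s * tm.sampling_rate_hz)))
    wlen = max(3, int(round(10.0 * tm.sampling_rate_hz)))
    times, amps = [], []
    for row in tm.dff:
        sd = _robust_noise_sd(row)
        if sd == 0:
            continue_empty = np.array([])
            times.append(continue_empty + tm.t0_s)
            amps.append(continue_empty)
            continue
        thr = min_prominence * sd
        idx, _ = find_peaks(row, height=thr, prominence=thr, wlen=wlen, distance=distance)
        times.append(tm.t0_s + idx / tm.sampling_rate_hz)
        amps.append(row[idx])
    return EventTrain(cell_ids=list(tm.cell_ids), times=times, amplitudes=amps)


def align_responses(
    tm: TraceMatrix,
    anchors: Sequence[float],
    pre_s: float = 5.0,
    post_s: float = 5.0,
) -> AlignedResponse:
    """Slice ΔF/F₀ around each anchor into a trials x cells x bins tensor.

    The anchor sample is the nearest sample at or before the anchor time;
    the window is ``[anchor - pre_s, anchor + post_s)`` in half-open sample
    coordinates. Anchors whose window leaves the trace are dropped and
    logged.
    """
    if tm.dff is None:
        raise ValueError("compute_dff first")
    rate = tm.sampling_rate_hz
    n_pre = int(round(pre_s * rate))
    n_post = int(round(post_s * rate))
    n_bins = n_pre + n_post
    kept, slabs = [], []
    for t in np.asarray(anchors, dtype=float):
        c = tm.time_to_sample(t)
        lo, hi = c - n_pre, c + n_post
        if lo < 0 or hi > tm.n_samples:
            continue
        kept.append(t)
        slabs.append(tm.dff[:, lo:hi])
    dropped = len(anchors) - len(kept)
    if dropped:
        logger.info("align_responses: dropped %d/%d edge-clipped trials", dropped, len(anchors))
    if not kept:
        tensor = np.empty((0, tm.n_cells, n_bins))
    else:
        tensor = np.stack(slabs)
    return AlignedResponse(
        tensor=tensor, anchors=np.array(kept), pre_s=pre_s, post_s=post_s, bin_s=1.0 / rate
    )


def event_probability(
    events: EventTrain,
    anchors: Sequence[float],
    pre_s: float = 5.0,
    post_s: float = 5.0,
    bin_s: float = 0.1,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cell probability that a trial has >= 1 event in each peri-anchor bin.

    Returns ``(curves, bin_edges)`` where curves is cells x bins with
    values in [0, 1] and bin_edges are times relative to the anchor.
    """
    anchors = np.asarray(anchors, dtype=float)
    if anchors.size == 0:
        raise ValueError("need at least one anchor")
    edges = np.arange(-pre_s, post_s + bin_s / 2, bin_s)
    n_bins = len(edges) - 1
    curves = np.zeros((len(events.cell_ids), n_bins))
    for ci, times in enumerate(events.times):
        for a in anchors:
            rel = times - a
            hit, _ = np.histogram(rel, bins=edges)
            curves[ci] += hit > 0
    curves /= anchors.size
    return curves, edges


def spontaneous_epochs(
    press_times: Sequence[float], duration_s: float, margin_s: float = 10.0
) -> List[Tuple[float, float]]:
    """Intervals at least ``margin_s`` away from every press."""
    presses = np.asarray(press_times, dtype=float)
    if presses.size == 0:
        return [(0.0, duration_s)]
    epochs = []
    cursor = 0.0
    for p in presses:
        lo, hi = p - margin_s, p + margin_s
        if lo > cursor:
            epochs.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < duration_s:
        epochs.append((cursor, duration_s))
    return epochs


def _epoch_anchor_grid(
    epochs: Sequence[Tuple[float, float]], n_anchors: int, pre_s: float, post_s: float
) -> np.ndarray:
    """Deterministic evenly spaced anchors inside epochs wide enough for the window."""
    usable = [(a + pre_s, b - post_s) for a, b in epochs if (b - post_s) > (a + pre_s)]
    if not usable:
        return np.array([])
    total = sum(b - a for a, b in usable)
    offsets = (np.arange(n_anchors) + 0.5) / n_anchors * total
    anchors = []
    for off in offsets:
        for a, b in usable:
            if off <= b - a:
                anchors.append(a + off)
                break
            off -= b - a
    return np.array(anchors)


def action_locked_peak(
    tm: TraceMatrix,
    aligned: AlignedResponse,
    spont_epochs: Sequence[Tuple[float, float]],
    n_spont_anchors: Optional[int] = None,
) -> PethSummary:
    """Peak of the trial-averaged action-locked response, normalized to the
    peak of the same statistic over spontaneous-epoch anchors.

    Spontaneous anchors are an evenly spaced deterministic grid inside the
    given epochs (same count as action trials unless overridden). Raises if
    the spontaneous reference peak is zero for any cell.
    """
    mean_curves = aligned.mean_curves()
    bt = aligned.bin_times
    peak_idx = np.argmax(mean_curves, axis=1)
    peak_value = mean_curves[np.arange(mean_curves.shape[0]), peak_idx]
    peak_latency = bt[peak_idx]

    n_anchors = n_spont_anchors or max(10, len(aligned.anchors))
    spont_anchors = _epoch_anchor_grid(spont_epochs, n_anchors, aligned.pre_s, aligned.post_s)
    if spont_anchors.size == 0:
        raise ValueError("no spontaneous epoch wide enough for the alignment window")
    spont = align_responses(tm, spont_anchors, pre_s=aligned.pre_s, post_s=aligned.post_s)
    spont_peak = spont.mean_curves().max(axis=1)
    if np.any(spont_peak <= 0):
        bad = [tm.cell_ids[i] for i in np.flatnonzero(spont_peak <= 0)]
        raise ValueError(f"zero/negative spontaneous peak for cells {bad}")
    return PethSummary(
        cell_ids=list(tm.cell_ids),
        mean_curves=mean_curves,
        bin_times=bt,
        peak_value=peak_value,
        peak_latency_s=peak_latency,
        spontaneous_peak=spont_peak,
        normalized_peak=peak_value / spont_peak,
    )


def pairwise_correlation(
    tm: TraceMatrix, anchors: Sequence[float], window_s: float = 10.0
) -> Tuple[np.ndarray, float]:
    """Pearson correlation between cells in press-centered windows.

    For each anchor, correlations are computed over the ``window_s`` window
    centered on it, then averaged across anchors. Returns the symmetric
    matrix (unit diagonal) and the mean off-diagonal coefficient — a
    descriptive measure of population synchrony. A zero-variance window
    marks its pairs NaN for that anchor; NaN pairs are excluded from
    averages (logged).
    """
    if tm.dff is None:
        raise ValueError("compute_dff first")
    if tm.n_cells < 2:
        raise ValueError("need >= 2 cells")
    half = window_s / 2.0
    mats = []
    for t in np.asarray(anchors, dtype=float):
        lo = tm.time_to_sample(t - half)
        hi = lo + int(round(window_s * tm.sampling_rate_hz))
        if lo < 0 or hi > tm.n_samples:
            continue
        seg = tm.dff[:, lo:hi]
        sd = seg.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(seg)
        C[sd == 0, :] = np.nan
        C[:, sd == 0] = np.nan
        mats.append(C)
    if not mats:
        raise ValueError("no anchor window fits inside the trace")
    stack = np.stack(mats)
    n_nan = int(np.isnan(stack).sum())
    if n_nan:
        logger.info("pairwise_correlation: %d NaN pair-window entries excluded", n_nan)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs stay NaN
        mean_mat = np.nanmean(stack, axis=0)
    np.fill_diagonal(mean_mat, 1.0)
    off = mean_mat[~np.eye(tm.n_cells, dtype=bool)]
    mean_off = float(np.nanmean(off))
    return mean_mat, mean_off
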