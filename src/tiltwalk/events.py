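"""Gait-event detection and walking-segment separation.

Events are read off the smoothed sagittal-plane angular velocity of each
ankle: the dominant positive peak of a stride is the mid-swing, the
lowest valley right before it the toe-off, and the first zero-crossing
after it the heel strike.  Strides of both feet are then merged and split
into walking segments wherever consecutive gait cycles are >= 2 s apart
(the experimenter-imposed turns at the hall boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks, freqz

logger = logging.getLogger(__name__)

__all__ = [
    "GaitEvents",
    "WalkingSegment",
    "lowpass",
    "lowpass_response_db",
    "detect_midswing",
    "detect_toeoff",
    "detect_heelstrike",
    "extract_gait_events",
    "segment_walking",
]

LOWPASS_CUTOFF_HZ = 12.0
LOWPASS_ORDER = 4
MIN_PEAK_SEPARATION_S = 0.4     # physiologic cadence bound (2.5 strides/s/foot)
THRESHOLD_QUANTILE = 95.0
THRESHOLD_FRACTION = 0.4
TOEOFF_LOOKBACK_S = 0.8
SEGMENT_GAP_S = 2.0
MIN_STRIDES_PER_SEGMENT = 3


@dataclass
class GaitEvents:
    """Per-foot stride events as 0-based sample indices.

    Arrays are index-aligned: stride ``i`` is the triple
    ``(toeoff_idx[i], midswing_idx[i], heelstrike_idx[i])`` and the
    ordering invariant toe-off < mid-swing < heel-strike holds for every
    stride.
    """

    foot: str
    toeoff_idx: np.ndarray
    midswing_idx: np.ndarray
    heelstrike_idx: np.ndarray
    sample_rate_hz: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.toeoff_idx = np.asarray(self.toeoff_idx, dtype=int)
        self.midswing_idx = np.asarray(self.midswing_idx, dtype=int)
        self.heelstrike_idx = np.asarray(self.heelstrike_idx, dtype=int)
        if not (self.toeoff_idx.size == self.midswing_idx.size == self.heelstrike_idx.size):
            raise ValueError("event arrays must be index-aligned")
        if np.any(np.diff(self.midswing_idx) <= 0):
            raise ValueError("mid-swing indices must be strictly increasing")
        order_ok = (self.toeoff_idx < self.midswing_idx) & \
                   (self.midswing_idx < self.heelstrike_idx)
        if not np.all(order_ok):
            raise ValueError("event order violated: need toe-off < mid-swing < heel-strike")

    @property
    def n_strides(self) -> int:
        return int(self.midswing_idx.size)

    def times(self, which: str) -> np.ndarray:
        idx = getattr(self, f"{which}_idx")
        return self.t0 + idx / self.sample_rate_hz


@dataclass
class WalkingSegment:
    """A contiguous stretch of strides between turns (half-open samples)."""

    index: int                      # 1-based: WS1, WS2, ...
    start_idx: int
    end_idx: int
    strides: dict[str, np.ndarray] = field(default_factory=dict)  # foot -> stride ids

    @property
    def n_strides(self) -> int:
        return sum(int(v.size) for v in self.strides.values())


def lowpass(signal: np.ndarray, sample_rate: float,
            cutoff_hz: float = LOWPASS_CUTOFF_HZ,
            order: int = LOWPASS_ORDER) -> np.ndarray:
    """Zero-phase fourth-order Butterworth low-pass at 12 Hz.

    Forward-backward filtering keeps event timestamps phase-true; the
    effective magnitude response is the squared single-pass response.
    """
    if sample_rate <= 2 * cutoff_hz:
        raise ValueError("sample rate must exceed twice the cut-off frequency")
    x = np.asarray(signal, dtype=float)
    b, a = butter(order, cutoff_hz, fs=sample_rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.size <= padlen:
        raise ValueError(
            f"signal of {x.size} samples shorter than filter warm-up ({padlen + 1})"
        )
    return filtfilt(b, a, x)


def lowpass_response_db(freq_hz: float, sample_rate: float,
                        cutoff_hz: float = LOWPASS_CUTOFF_HZ,
                        order: int = LOWPASS_ORDER) -> float:
    """Analytic two-pass (zero-phase) magnitude response in dB at ``freq_hz``."""
    b, a = butter(order, cutoff_hz, fs=sample_rate)
    _, h = freqz(b, a, worN=[freq_hz], fs=sample_rate)
    return float(20.0 * np.log10(np.abs(h[0]) ** 2))


def detect_midswing(smoothed: np.ndarray, sample_rate: float,
                    threshold: float | None = None,
                    min_separation_s: float = MIN_PEAK_SEPARATION_S) -> np.ndarray:
    """Mid-swing peaks: local maxima above a per-trial adaptive threshold.

    The threshold defaults to 0.4x the 95th percentile of the positive
    part of the smoothed signal - a scale-free rule standing in for the
    trial-specific thresholds a human rater would pick.  Peaks closer
    than ``min_separation_s`` keep only the larger one.
    """
    x = np.asarray(smoothed, dtype=float)
    if threshold is None:
        pos = x[x > 0]
        if pos.size == 0:
            return np.array([], dtype=int)
        threshold = THRESHOLD_FRACTION * np.percentile(pos, THRESHOLD_QUANTILE)
    distance = max(1, int(round(min_separation_s * sample_rate)))
    peaks, _ = find_peaks(x, height=threshold, distance=distance)
    return peaks.astype(int)


def detect_toeoff(smoothed: np.ndarray, midswing_idx: np.ndarray,
                  sample_rate: float,
                  lookback_s: float = TOEOFF_LOOKBACK_S) -> np.ndarray:
    """Toe-off: minimum in the window just before each mid-swing.

    The window runs from the previous mid-swing (or ``lookback_s`` before
    the current one, whichever is later) up to the mid-swing.  Strides
    whose window is empty are marked with -1 and dropped by callers.
    """
    x = np.asarray(smoothed, dtype=float)
    ms = np.asarray(midswing_idx, dtype=int)
    lookback = max(1, int(round(lookback_s * sample_rate)))
    out = np.full(ms.size, -1, dtype=int)
    for i, m in enumerate(ms):
        lo = max(0, m - lookback)
        if i > 0:
            lo = max(lo, ms[i - 1] + 1)
        if lo >= m:
            logger.warning("toe-off window empty for mid-swing at sample %d; stride dropped", m)
            continue
        out[i] = lo + int(np.argmin(x[lo:m]))
    return out


def detect_heelstrike(smoothed: np.ndarray, midswing_idx: np.ndarray,
                      next_limit: np.ndarray | None = None) -> np.ndarray:
    """Heel strike: the datapoint at the first positive-to-nonpositive
    zero-crossing after each mid-swing peak.

    The crossing instant is located by linear interpolation between the
    last positive and first non-positive sample, and the nearer of the
    two samples is reported, so the index is unbiased with respect to the
    true crossing.  Strides with no crossing before the next mid-swing
    (or trace end) are marked -1.
    """
    x = np.asarray(smoothed, dtype=float)
    ms = np.asarray(midswing_idx, dtype=int)
    out = np.full(ms.size, -1, dtype=int)
    nonpos = x <= 0
    for i, m in enumerate(ms):
        hi = x.size if next_limit is None else int(next_limit[i])
        if i + 1 < ms.size:
            hi = min(hi, ms[i + 1])
        rel = np.flatnonzero(nonpos[m:hi])
        if rel.size == 0:
            logger.warning("no zero-crossing after mid-swing at sample %d; stride dropped", m)
            continue
        j = m + int(rel[0])
        if j > m and x[j - 1] > 0 > x[j]:
            # fractional crossing position within [j-1, j]
            frac = x[j - 1] / (x[j - 1] - x[j])
            if frac < 0.5:
                j -= 1
        out[i] = max(j, m + 1)
    return out


def extract_gait_events(smoothed: np.ndarray, sample_rate: float, foot: str,
                        t0: float = 0.0, **midswing_kwargs) -> GaitEvents:
    """Full per-foot event extraction on an already-smoothed signal."""
    ms = detect_midswing(smoothed, sample_rate, **midswing_kwargs)
    to = detect_toeoff(smoothed, ms, sample_rate)
    hs = detect_heelstrike(smoothed, ms)
    keep = (to >= 0) & (hs >= 0)
    n_drop = int(np.sum(~keep))
    if n_drop:
        logger.info("%s: dropped %d incomplete strides", foot, n_drop)
    return GaitEvents(foot, to[keep], ms[keep], hs[keep], sample_rate, t0)


def segment_walking(events_left: GaitEvents, events_right: GaitEvents,
                    min_gap_s: float = SEGMENT_GAP_S,
                    min_strides: int = MIN_STRIDES_PER_SEGMENT) -> list[WalkingSegment]:
    """Split the merged bilateral stride sequence into walking segments.

    Both feet's mid-swing times are merged and a new segment starts
    wherever consecutive mid-swings are >= ``min_gap_s`` apart.  Segments
    with fewer than ``min_strides`` strides (first/last steps of a turn
    are too variable to regress on) are discarded with a log entry;
    remaining segments are renumbered 1..k in temporal order.
    """
    if events_left.sample_rate_hz != events_right.sample_rate_hz:
        raise ValueError("feet must share a sample rate")
    feet = {"left": events_left, "right": events_right}
    ms_times = []
    for foot, ev in feet.items():
        tms = ev.times("midswing")
        ms_times.append(np.column_stack([
            tms, np.full(tms.size, 1.0 if foot == "right" else 0.0),
            np.arange(tms.size, dtype=float),
        ]))
    merged = np.concatenate(ms_times)
    if merged.size == 0:
        return []
    merged = merged[np.argsort(merged[:, 0], kind="stable")]
    breaks = np.flatnonzero(np.diff(merged[:, 0]) >= min_gap_s) + 1
    groups = np.split(np.arange(merged.shape[0]), breaks)

    segments: list[WalkingSegment] = []
    for rows in groups:
        sub = merged[rows]
        if sub.shape[0] < min_strides:
            logger.info("discarding segment with %d strides (< %d)",
                        sub.shape[0], min_strides)
            continue
        strides = {}
        lo, hi = None, None
        for foot, ev in feet.items():
            flag = 1.0 if foot == "right" else 0.0
            ids = sub[sub[:, 1] == flag, 2].astype(int)
            strides[foot] = ids
            if ids.size:
                lo_f = int(ev.toeoff_idx[ids].min())
                hi_f = int(ev.heelstrike_idx[ids].max()) + 1
                lo = lo_f if lo is None else min(lo, lo_f)
                hi = hi_f if hi is None else max(hi, hi_f)
        segments.append(WalkingSegment(0, lo, hi, strides))
    for i, seg in enumerate(segments, start=1):
        seg.index = i
    return segments
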