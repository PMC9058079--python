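"""Pre-processing of raw sensor traces.

Two independent recording systems (body-worn inertial trackers and
pressure-sensing shoe insoles) are aligned on a common clock using the
leg-slap synchronization event performed at the start of every trial, and
short dropouts in either system are repaired by shape-preserving
piecewise-cubic interpolation.

No clock-skew estimation is attempted: the systems are aligned by a single
offset and any residual drift is handled downstream by running gait-event
detection on each system separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import Akima1DInterpolator

logger = logging.getLogger(__name__)

__all__ = [
    "SensorTrace",
    "SyncNotFoundError",
    "detect_slap",
    "synchronize",
    "fill_gaps",
]


class SyncNotFoundError(RuntimeError):
    """No medio-lateral acceleration peak exceeded the slap threshold.

    Raised when the synchronization event cannot be located; the trial is
    unusable because the two sensor systems cannot be put on a common clock.
    """


@dataclass
class SensorTrace:
    """Uniformly sampled multichannel time series from one device.

    Parameters
    ----------
    timestamps
        Sample times in seconds, strictly increasing, nominally uniform.
    channels
        Mapping of channel name to a 1-D signal array, all the same length
        as ``timestamps``.  Missing samples hold NaN and are flagged in
        ``missing_mask``.
    units
        Declared unit per channel (e.g. ``"m/s^2"``, ``"deg/s"``,
        ``"norm"``).  Every channel must have one.
    missing_mask
        Boolean array, True where a sample is missing.
    device_id, body_location
        Free-form labels identifying the physical sensor.
    """

    timestamps: np.ndarray
    channels: dict[str, np.ndarray]
    units: dict[str, str]
    missing_mask: np.ndarray | None = None
    device_id: str = ""
    body_location: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.timestamps.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    # -- basic integrity -------------------------------------------------
    def validate(self) -> None:
        n = self.timestamps.size
        if n < 2:
            raise ValueError("trace needs at least two samples")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.missing_mask.size != n:
            raise ValueError("missing_mask length mismatch")
        for name, sig in self.channels.items():
            sig = np.asarray(sig, dtype=float)
            self.channels[name] = sig
            if sig.size != n:
                raise ValueError(f"channel {name!r} length mismatch")
            if name not in self.units:
                raise ValueError(f"channel {name!r} has no declared unit")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    @property
    def n_samples(self) -> int:
        return int(self.timestamps.size)

    def copy(self) -> "SensorTrace":
        return replace(
            self,
            timestamps=self.timestamps.copy(),
            channels={k: v.copy() for k, v in self.channels.items()},
            units=dict(self.units),
            missing_mask=self.missing_mask.copy(),
            meta=dict(self.meta),
        )


def detect_slap(
    accel_ml: np.ndarray,
    sample_rate: float,
    threshold: float | None = None,
    search_window_s: tuple[float, float] | None = None,
    t0: float = 0.0,
) -> float:
    """Locate the leg-slap synchronization impulse.

    The slap produces a dominant transient in the absolute medio-lateral
    acceleration.  Within the search window the time of the largest
    absolute peak exceeding ``threshold`` is returned.

    Parameters
    ----------
    accel_ml
        Medio-lateral acceleration signal.
    sample_rate
        Sampling rate in Hz.
    threshold
        Absolute-acceleration threshold.  Default: 10x the median absolute
        deviation of the windowed signal, a robust scale that separates the
        slap (by protocol an order of magnitude above walking accelerations)
        from gait transients.
    search_window_s
        ``(start, stop)`` window in trace time; default is the whole trace.
    t0
        Time of the first sample, used to express the result in trace time.

    Returns
    -------
    float
        Slap time in seconds (sample-resolution).

    Raises
    ------
    SyncNotFoundError
        If no sample in the window exceeds the threshold.
    """
    x = np.abs(np.asarray(accel_ml, dtype=float))
    n = x.size
    if search_window_s is None:
        lo, hi = 0, n
    else:
        lo = max(0, int(np.ceil((search_window_s[0] - t0) * sample_rate)))
        hi = min(n, int(np.floor((search_window_s[1] - t0) * sample_rate)) + 1)
    if hi <= lo:
        raise ValueError("search window outside trace extent")
    win = x[lo:hi]
    win = np.where(np.isnan(win), 0.0, win)
    if threshold is None:
        med = np.median(win)
        threshold = 10.0 * np.median(np.abs(win - med))
    if threshold < 0:
        raise ValueError("threshold must be positive")
    above = win > threshold
    if not np.any(above):
        raise SyncNotFoundError(
            f"no |ML acceleration| peak above {threshold:.3g} in search window"
        )
    idx = lo + int(np.argmax(np.where(above, win, -np.inf)))
    return t0 + idx / sample_rate


def synchronize(
    trace_a: SensorTrace,
    trace_b: SensorTrace,
    slap_a: float,
    slap_b: float,
    crop_to_overlap: bool = False,
) -> tuple[SensorTrace, SensorTrace]:
    """Put ``trace_b`` on ``trace_a``'s clock via the common slap event.

    ``trace_b``'s timestamps are shifted by ``slap_a - slap_b``; sample
    values are never resampled.  With ``crop_to_overlap`` both traces are
    cut to their common time span.

    Raises
    ------
    ValueError
        If the shifted traces do not overlap in time.
    """
    shift = slap_a - slap_b
    b = trace_b.copy()
    # shifts accumulate against the raw clock so that applying the
    # negative offset restores the original timestamps bit-for-bit
    raw = b.meta.get("_raw_timestamps", trace_b.timestamps)
    prev = b.meta.get("sync_offset_s", 0.0)
    total = prev + shift
    b.meta["_raw_timestamps"] = raw
    b.timestamps = raw + total if total != 0.0 else raw.copy()
    b.meta["sync_offset_s"] = total
    a = trace_a.copy()
    t_lo = max(a.timestamps[0], b.timestamps[0])
    t_hi = min(a.timestamps[-1], b.timestamps[-1])
    if t_hi <= t_lo:
        raise ValueError("traces do not overlap after synchronization shift")
    if crop_to_overlap:
        for tr in (a, b):
            keep = (tr.timestamps >= t_lo) & (tr.timestamps <= t_hi)
            tr.timestamps = tr.timestamps[keep]
            tr.missing_mask = tr.missing_mask[keep]
            for name in tr.channels:
                tr.channels[name] = tr.channels[name][keep]
            tr.meta.pop("_raw_timestamps", None)   # raw clock no longer aligned
    logger.info("synchronized %s to %s: offset %+.4f s", b.device_id, a.device_id, shift)
    return a, b


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True in ``mask`` as half-open (start, stop)."""
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    for s, e in zip(idx[::2], idx[1::2]):
        runs.append((int(s), int(e)))
    return runs


def fill_gaps(trace: SensorTrace, max_gap_s: float = 0.2) -> SensorTrace:
    """Repair short dropouts by modified-Akima piecewise-cubic interpolation.

    Gaps no longer than ``max_gap_s`` are filled per channel with a
    shape-preserving cubic Hermite spline (makima) built on the observed
    samples; observed samples are never modified.  Longer gaps, and gaps
    touching a trace boundary (no extrapolation), are left missing and
    recorded in ``meta["unfilled_gaps"]`` as ``(start_idx, stop_idx)``.

    Interpolating across long gaps would fabricate gait structure, hence
    the conservative default of 0.2 s.
    """
    out = trace.copy()
    runs = _missing_runs(out.missing_mask)
    if not runs:
        return out
    t = out.timestamps
    n = t.size
    fill: list[tuple[int, int]] = []
    unfilled: list[tuple[int, int]] = []
    for s, e in runs:
        gap_len_s = t[min(e, n - 1)] - t[max(s - 1, 0)]
        boundary = s == 0 or e == n
        if boundary or gap_len_s > max_gap_s + 1e-12:
            unfilled.append((s, e))
            if boundary:
                logger.warning("gap at trace boundary [%d:%d) left missing", s, e)
            else:
                logger.warning(
                    "gap of %.3f s at [%d:%d) exceeds max_gap_s=%.3f, left missing",
                    gap_len_s, s, e, max_gap_s,
                )
        else:
            fill.append((s, e))
    if fill:
        obs = ~out.missing_mask
        for name, sig in out.channels.items():
            interp = Akima1DInterpolator(t[obs], sig[obs], method="makima")
            for s, e in fill:
                out.channels[name][s:e] = interp(t[s:e])
        for s, e in fill:
            out.missing_mask[s:e] = False
    out.meta["unfilled_gaps"] = unfilled
    return out
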