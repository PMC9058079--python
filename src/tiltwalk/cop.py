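"""Plantar centre-of-pressure (CoP) statistics from sensor insoles.

The CoP of a pressure frame is the pressure-weighted centroid of the 16
sensor positions.  Per step, the CoP is averaged (force-weighted) over
the stance phase; per walking segment, step values are averaged
unweighted; and the left-right lateral symmetry

    CoP_LM_Sym = CoP_LM_left - CoP_LM_right

summarizes weight distribution: negative values mean a disequilibrium to
the left, positive to the right.

Frame convention: insole coordinates are normalized to -0.5..0.5 with x
positive posterior->anterior.  The two devices' lateral axes point in
opposite anatomical directions, so the right insole's lateral axis is
mirrored at load time; after that, y is positive toward medial on BOTH
feet and the symmetry statistic is a pure left-minus-right contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .events import GaitEvents, WalkingSegment
from .preprocess import SensorTrace

logger = logging.getLogger(__name__)

__all__ = [
    "CopSeries",
    "CopMeasures",
    "sample_cop",
    "cop_series",
    "stance_windows",
    "step_cop",
    "ws_cop",
    "cop_sym",
    "CONTACT_THRESHOLD_FRACTION",
]

CONTACT_THRESHOLD_FRACTION = 0.05   # of the trial's 95th-percentile total force
PRESSURE_CHANNELS = [f"p{i:02d}" for i in range(16)]


def sample_cop(pressures: np.ndarray, positions: np.ndarray
               ) -> tuple[float, float, float] | None:
    """CoP of one pressure frame.

    Returns ``(cop_x, cop_y, total_force)`` - the pressure-weighted
    centroid of the sensor positions - or ``None`` for an all-zero frame
    (swing phase, CoP undefined).
    """
    p = np.asarray(pressures, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressures must be non-negative")
    total = float(p.sum())
    if total <= 0.0:
        return None
    x = float(p @ positions[:, 0] / total)
    y = float(p @ positions[:, 1] / total)
    return x, y, total


@dataclass
class CopSeries:
    """Per-sample CoP trajectory of one insole in the anatomical frame."""

    cop_pa: np.ndarray     # posterior->anterior, positive forward
    cop_lm: np.ndarray     # positive toward medial (both feet)
    force: np.ndarray
    timestamps: np.ndarray
    foot: str


def cop_series(insole: SensorTrace, foot: str,
               positions: np.ndarray | None = None) -> CopSeries:
    """Per-sample CoP from a raw insole trace, mirrored to the anatomical
    frame (right foot's device lateral axis is flipped)."""
    if positions is None:
        from .synthgait import INSOLE_POSITIONS
        positions = INSOLE_POSITIONS
    press = np.column_stack([insole.channels[c] for c in PRESSURE_CHANNELS])
    press = np.where(np.isnan(press), 0.0, press)
    total = press.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = press @ positions[:, 0] / total
        y = press @ positions[:, 1] / total
    x[total <= 0] = np.nan
    y[total <= 0] = np.nan
    if foot == "right":
        y = -y
    elif foot != "left":
        raise ValueError("foot must be 'left' or 'right'")
    return CopSeries(cop_pa=x, cop_lm=y, force=total,
                     timestamps=insole.timestamps, foot=foot)


def stance_windows(ev: GaitEvents) -> list[tuple[int, int]]:
    """Stance phases as half-open sample windows: same-foot heel strike to
    the subsequent same-foot toe-off (last stance runs to the last
    heel-strike's segment end and is bounded by the caller)."""
    out = []
    for i, hs in enumerate(ev.heelstrike_idx):
        if i + 1 < ev.n_strides:
            out.append((int(hs), int(ev.toeoff_idx[i + 1])))
    return out


def step_cop(series: CopSeries, window: tuple[int, int],
             contact_threshold: float) -> tuple[float, float] | None:
    """Force-weighted mean CoP over one stance window.

    Only samples whose total force exceeds ``contact_threshold`` count as
    loaded.  Returns ``(mean_lm, mean_pa)`` or ``None`` (step skipped)
    when no sample in the window is loaded.
    """
    lo, hi = window
    f = series.force[lo:hi]
    loaded = f > contact_threshold
    if not np.any(loaded):
        logger.info("no loaded samples in stance window [%d:%d); step skipped", lo, hi)
        return None
    w = f[loaded]
    lm = float(np.average(series.cop_lm[lo:hi][loaded], weights=w))
    pa = float(np.average(series.cop_pa[lo:hi][loaded], weights=w))
    return lm, pa


def contact_threshold_for(series: CopSeries) -> float:
    """Default contact threshold: 5% of the trial's 95th-percentile force."""
    f = series.force[series.force > 0]
    if f.size == 0:
        return 0.0
    return CONTACT_THRESHOLD_FRACTION * float(np.percentile(f, 95))


@dataclass
class CopMeasures:
    """Per-foot walking-segment summary of lateral and fore-aft CoP."""

    ws_index: int
    foot: str
    mean_lm: float
    sd_lm: float
    mean_pa: float
    sd_pa: float
    n_steps: int


def ws_cop(step_values: list[tuple[float, float]], segment: WalkingSegment,
           foot: str) -> CopMeasures | None:
    """Unweighted mean and SD over a segment's step CoP values.

    With a single step the SD is reported as 0 by convention.  Returns
    ``None`` when the segment has no valid steps for this foot.
    """
    if not step_values:
        logger.info("WS%d %s: no valid steps, CoP missing", segment.index, foot)
        return None
    arr = np.asarray(step_values, dtype=float)
    lm, pa = arr[:, 0], arr[:, 1]
    ddof = 1 if arr.shape[0] > 1 else 0
    return CopMeasures(
        ws_index=segment.index, foot=foot,
        mean_lm=float(lm.mean()), sd_lm=float(lm.std(ddof=ddof)),
        mean_pa=float(pa.mean()), sd_pa=float(pa.std(ddof=ddof)),
        n_steps=int(arr.shape[0]),
    )


def cop_sym(left_mean_lm: float | None, right_mean_lm: float | None) -> float | None:
    """Lateral CoP symmetry: left minus right mean lateral CoP.

    Negative = disequilibrium to the left, positive = to the right.
    Missing data on either foot yields a missing result (the trial is
    excluded from CoP analyses).
    """
    if left_mean_lm is None or right_mean_lm is None:
        return None
    return float(left_mean_lm - right_mean_lm)
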