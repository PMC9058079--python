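"""Chest orientation estimation and per-segment heading (yaw) slope.

Gyroscope angular rates are integrated through the exact ZYX Euler-angle
kinematics while the accelerometer's gravity direction slowly corrects
the two tilt angles (pitch, roll) with a complementary-filter gain.  The
heading (yaw) is pure gyro integration from an identity start - no
magnetometer is used, so absolute heading is meaningless but heading
*change* within a walking segment, which is what the analysis needs, is
well defined.

Axis convention: body z is cranio-caudal (up), x anterior, y to the left;
yaw is the rotation about z with positive = leftward chest rotation.
Walking keeps pitch far from +-90 deg, so gimbal lock is not handled
beyond an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import linregress

from .events import WalkingSegment

__all__ = ["OrientationSeries", "YawSlope", "fuse", "yaw_slope", "unwrap_deg"]

TILT_TAU_S = 1.0   # complementary-filter tilt-correction time constant


@dataclass
class OrientationSeries:
    """Estimated orientation per sample.

    ``quat`` is scalar-last (x, y, z, w), unit norm; Euler angles are in
    degrees, intrinsic yaw-pitch-roll (rotation about cranio-caudal, then
    medio-lateral, then anterior-posterior axes).
    """

    quat: np.ndarray
    yaw_deg: np.ndarray
    pitch_deg: np.ndarray
    roll_deg: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.quat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions must be unit norm")


@dataclass
class YawSlope:
    """OLS fit of unwrapped yaw against time over one walking segment."""

    ws_index: int
    slope_deg_per_s: float
    intercept_deg: float
    n_samples: int
    residual_sd_deg: float


def _wrap_pi(x: float) -> float:
    return (x + np.pi) % (2.0 * np.pi) - np.pi


def fuse(gyro_deg_s: np.ndarray, accel: np.ndarray, sample_rate: float,
         tilt_tau_s: float = TILT_TAU_S) -> OrientationSeries:
    """Fuse 3-axis gyroscope and accelerometer into an orientation series.

    Parameters
    ----------
    gyro_deg_s : (n, 3) array
        Body angular rates about (x, y, z) in deg/s.
    accel : (n, 3) array
        Specific force in the body frame; only its direction is used, so
        either m/s^2 or g units work.  Static and upright it points along
        +z (cranio-caudal).
    sample_rate : float
        Hz.
    tilt_tau_s : float
        Time constant of the first-order pull of pitch/roll toward the
        accelerometer's gravity direction.  The correction acts on the
        tilt angles only; yaw is untouched gyro integration starting at
        identity (sensors are reset in neutral standing pose).

    Notes
    -----
    Zero-norm accelerometer samples are skipped for the correction (the
    step is then gyro-only).  NaN samples (masked dropouts that were too
    long to fill) are treated as zero rate / no correction.
    """
    g = np.deg2rad(np.asarray(gyro_deg_s, dtype=float))
    a = np.asarray(accel, dtype=float)
    if g.shape != a.shape or g.ndim != 2 or g.shape[1] != 3:
        raise ValueError("gyro and accel must both be (n, 3)")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    n = g.shape[0]
    dt = 1.0 / sample_rate
    alpha = dt / (tilt_tau_s + dt)

    phi = 0.0    # roll, about x
    theta = 0.0  # pitch, about y
    psi = 0.0    # yaw, about z
    euler = np.empty((n, 3))
    euler[0] = (psi, theta, phi)
    for i in range(1, n):
        p, q, r = g[i]
        if np.isnan(p) or np.isnan(q) or np.isnan(r):
            p = q = r = 0.0
        sphi, cphi = np.sin(phi), np.cos(phi)
        tth = np.tan(theta)
        cth = np.cos(theta)
        phi += dt * (p + sphi * tth * q + cphi * tth * r)
        theta += dt * (cphi * q - sphi * r)
        psi += dt * (sphi * q + cphi * r) / cth
        ax, ay, az = a[i]
        nrm = np.sqrt(ax * ax + ay * ay + az * az)
        if nrm > 1e-9 and not np.isnan(nrm):
            phi_acc = np.arctan2(ay, az)
            theta_acc = np.arctan2(-ax, np.hypot(ay, az))
            phi += alpha * _wrap_pi(phi_acc - phi)
            theta += alpha * _wrap_pi(theta_acc - theta)
        euler[i] = (psi, theta, phi)

    quat = Rotation.from_euler("ZYX", euler).as_quat()
    yaw, pitch, roll = np.rad2deg(euler).T
    # store yaw wrapped into [-180, 180); consumers unwrap before regression
    yaw = (yaw + 180.0) % 360.0 - 180.0
    return OrientationSeries(
        quat=quat, yaw_deg=yaw, pitch_deg=pitch, roll_deg=roll,
        timestamps=np.arange(n) * dt,
    )


def unwrap_deg(yaw_deg: np.ndarray) -> np.ndarray:
    """Remove +-180 deg wrap-around jumps before regression."""
    return np.unwrap(np.asarray(yaw_deg, dtype=float), period=360.0)


def yaw_slope(orientation: OrientationSeries, segment: WalkingSegment) -> YawSlope:
    """Ordinary least-squares heading slope over one walking segment.

    All samples of the segment enter the regression (the twist
    oscillation visible in raw yaw averages out over whole strides);
    positive slope = drifting leftward.
    """
    lo, hi = segment.start_idx, segment.end_idx
    if hi - lo < 2:
        raise ValueError("segment must span at least 2 samples")
    y = unwrap_deg(orientation.yaw_deg[lo:hi])
    t = orientation.timestamps[lo:hi]
    fit = linregress(t, y)
    resid = y - (fit.intercept + fit.slope * t)
    return YawSlope(
        ws_index=segment.index,
        slope_deg_per_s=float(fit.slope),
        intercept_deg=float(fit.intercept),
        n_samples=int(hi - lo),
        residual_sd_deg=float(np.std(resid, ddof=2)) if hi - lo > 2 else 0.0,
    )
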