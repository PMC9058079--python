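"""Synthetic gait trials with exact ground truth.

Emulates the measurement setup of a roll-tilt adaptation walking study:
a chest IMU, two ankle IMUs and two 16-sensor pressure insoles (each with
an embedded IMU), all sampled at 100 Hz.  A trial consists of a leg-slap
synchronization impulse, a short standing phase, and several walking
segments separated by turn gaps of at least 2 s.

Every signal feature the analysis pipeline extracts is placed
analytically, so generated trials carry an exact :class:`GroundTruth`
(event times, segment bounds, per-segment yaw slope, CoP symmetry) against
which parameter recovery can be verified.

Design of the stride waveform
-----------------------------
Sagittal-plane ankle angular velocity is built from half-sine lobes per
stride of period ``T = 1/cadence`` (fractions of ``T`` after stride
start):

* toe-off valley, depth ``0.5 A``, minimum at ``0.12 T``;
* mid-swing peak, amplitude ``A``, maximum at ``0.32 T``;
* heel-strike zero-crossing at ``0.42 T`` (steep, so zero-phase filtering
  does not move it);
* a shallower post-heel-strike valley (depth ``0.3 A``) ending at
  ``0.62 T``.

Chest heading within a walking segment advances at a constant drift rate
plus a cosine-phased upper-body twist oscillation,
``amp * (cos(2*pi*k*(t-t0)/d) - 1)`` with an integer number of cycles
``k`` per segment, which is orthogonal to a linear trend: the ordinary
least-squares yaw slope of the noise-free signal equals the injected
drift rate exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import SensorTrace

__all__ = [
    "CONDITIONS",
    "SimConfig",
    "GroundTruth",
    "Trial",
    "StudyTrial",
    "simulate_trial",
    "simulate_study",
    "simulate_measure_table",
    "simulate_paired_measure_tables",
    "INSOLE_GRID",
    "INSOLE_POSITIONS",
]

CONDITIONS = ("baseline", "supine", "RED", "LED")

GRAVITY = 9.81  # m/s^2

# Stride-template geometry, as fractions of the stride period.
_TO_START, _TO_END = 0.02, 0.22     # toe-off valley support
_MS_START, _MS_END = 0.22, 0.42     # mid-swing lobe support
# Post-heel-strike valley: its entry slope matches the mid-swing lobe's
# exit slope (depth/width = 1/0.2), making the heel-strike zero-crossing
# locally odd-symmetric so zero-phase filtering does not displace it.
_PH_START, _PH_END = 0.42, 0.50     # post-heel-strike valley support
TOEOFF_FRAC = 0.12
MIDSWING_FRAC = 0.32
HEELSTRIKE_FRAC = 0.42
_TO_DEPTH = 0.5
_PH_DEPTH = 0.4

# 16 insole pressure sensors on a 4x4 grid of cell centres spanning the
# normalized -0.5..0.5 insole plane (the device reports sensor count, not
# geometry; the grid is this package's convention).
INSOLE_GRID = np.linspace(-0.375, 0.375, 4)
INSOLE_POSITIONS = np.array(
    [(INSOLE_GRID[ix], INSOLE_GRID[iy]) for iy in range(4) for ix in range(4)]
)  # columns: (x = posterior->anterior, y = lateral axis), device frame

_STANCE_END_FRAC = 1.0 + TOEOFF_FRAC   # stance: heel-strike -> next toe-off


def _default_drift() -> dict[str, float]:
    # deg/s; positive = leftward.  Ordering LED > supine > baseline > RED
    # with a small overall leftward bias, as observed in the study design
    # this generator emulates.
    return {"baseline": 0.1, "supine": 0.2, "RED": -0.4, "LED": 0.6}


def _default_cop_offset() -> dict[str, float]:
    # Normalized insole units of left-minus-right lateral CoP; sign opposes
    # the drift (leftward heading drift <-> leftward weight shift, negative).
    return {"baseline": 0.0, "supine": 0.0, "RED": 0.05, "LED": -0.05}


def _default_noise() -> dict[str, float]:
    return {"gyro": 1.0, "accel": 0.05, "pressure": 0.3}


@dataclass
class SimConfig:
    """Parameters of one simulated trial.

    Units: rates in Hz, times in s, angles in deg, angular velocity in
    deg/s, accelerations in m/s^2, CoP quantities in normalized insole
    units (range -0.5..0.5).
    """

    seed: int
    sample_rate_hz: float = 100.0
    cadence_hz: float = 0.9              # strides/s per foot
    walk_duration_s: float = 120.0       # total walking time over all segments
    n_segments: int = 5
    turn_gap_s: float = 3.0              # >= 2 s, separates walking segments
    drift_deg_per_s: dict[str, float] = field(default_factory=_default_drift)
    drift_decay_tau_s: float | None = None
    yaw_osc_amp_deg: float = 5.0
    yaw_osc_freq_hz: float = 1.8         # step-locked upper-body twist
    cop_offset: dict[str, float] = field(default_factory=_default_cop_offset)
    cop_base_lm: float = 0.0             # shared medial baseline of both feet
    noise_sd: dict[str, float] = field(default_factory=_default_noise)
    slap_time_s: float = 5.0
    stand_after_slap_s: float = 5.0
    stride_peak_deg_s: float = 200.0
    accel_ml_amp: float = 1.5            # walking medio-lateral accel wobble
    insole_clock_offset_s: float = 0.0   # insole clock minus IMU clock
    missing_gap_spec: list[tuple[float, float]] = field(default_factory=list)

    def validate(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.turn_gap_s < 2.0:
            raise ValueError("turn_gap_s must be >= 2 s (walking-segment rule)")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.yaw_osc_freq_hz >= self.sample_rate_hz / 2:
            raise ValueError("yaw oscillation frequency violates Nyquist limit")
        if self.cadence_hz <= 0 or self.walk_duration_s <= 0:
            raise ValueError("cadence and walk duration must be positive")

    # --- derived timeline (all boundaries snapped to the sample grid) ----
    def _snap(self, x: float) -> float:
        return round(x * self.sample_rate_hz) / self.sample_rate_hz

    @property
    def walk_start_s(self) -> float:
        return self._snap(self.slap_time_s + self.stand_after_slap_s)

    @property
    def segment_duration_s(self) -> float:
        return self._snap(self.walk_duration_s / self.n_segments)

    def segment_bounds(self) -> list[tuple[float, float]]:
        d = self.segment_duration_s
        gap = self._snap(self.turn_gap_s)
        out = []
        t0 = self.walk_start_s
        for _ in range(self.n_segments):
            out.append((t0, self._snap(t0 + d)))
            t0 = self._snap(t0 + d + gap)
        return out

    @property
    def total_duration_s(self) -> float:
        return self.segment_bounds()[-1][1] + 2.0


@dataclass
class GroundTruth:
    """Oracle labels for one simulated trial (times on the IMU clock, s)."""

    event_times: dict[str, dict[str, np.ndarray]]   # foot -> event -> times
    segment_bounds: list[tuple[float, float]]
    true_yaw_slope_per_ws: list[float]              # deg/s, one per segment
    true_cop_lm: dict[str, float]                   # anatomical frame, per foot
    true_cop_sym: float
    slap_time_s: float
    insole_clock_offset_s: float = 0.0

    def validate(self) -> None:
        for foot, ev in self.event_times.items():
            for name, times in ev.items():
                if np.any(np.diff(times) <= 0):
                    raise ValueError(f"{foot} {name} times not strictly increasing")
            for to, ms, hs in zip(ev["toeoff"], ev["midswing"], ev["heelstrike"]):
                if not (to < ms < hs):
                    raise ValueError("event order violated within a stride")
        for (a0, a1), (b0, b1) in zip(self.segment_bounds, self.segment_bounds[1:]):
            if b0 < a1:
                raise ValueError("segment bounds overlap")

    def to_json(self) -> str:
        payload = {
            "event_times": {
                foot: {k: v.tolist() for k, v in ev.items()}
                for foot, ev in self.event_times.items()
            },
            "segment_bounds": [list(b) for b in self.segment_bounds],
            "true_yaw_slope_per_ws": list(self.true_yaw_slope_per_ws),
            "true_cop_lm": self.true_cop_lm,
            "true_cop_sym": self.true_cop_sym,
            "slap_time_s": self.slap_time_s,
            "insole_clock_offset_s": self.insole_clock_offset_s,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            event_times={
                foot: {k: np.asarray(v, dtype=float) for k, v in ev.items()}
                for foot, ev in d["event_times"].items()
            },
            segment_bounds=[tuple(b) for b in d["segment_bounds"]],
            true_yaw_slope_per_ws=list(d["true_yaw_slope_per_ws"]),
            true_cop_lm=dict(d["true_cop_lm"]),
            true_cop_sym=float(d["true_cop_sym"]),
            slap_time_s=float(d["slap_time_s"]),
            insole_clock_offset_s=float(d.get("insole_clock_offset_s", 0.0)),
        )


@dataclass
class Trial:
    """One simulated trial: five sensor traces plus the oracle labels."""

    chest: SensorTrace
    ankle_left: SensorTrace
    ankle_right: SensorTrace
    insole_left: SensorTrace
    insole_right: SensorTrace
    truth: GroundTruth
    condition: str

    @property
    def traces(self) -> dict[str, SensorTrace]:
        return {
            "chest": self.chest,
            "ankle_left": self.ankle_left,
            "ankle_right": self.ankle_right,
            "insole_left": self.insole_left,
            "insole_right": self.insole_right,
        }


@dataclass
class StudyTrial:
    participant: str
    condition: str
    repetition: int
    trial: Trial


# ---------------------------------------------------------------------------
# stride waveform
# ---------------------------------------------------------------------------

def _half_sine(t: np.ndarray, start: float, end: float, amp: float) -> np.ndarray:
    """Half-sine lobe: zero outside [start, end], extremum ``amp`` at centre."""
    out = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    out[inside] = amp * np.sin(np.pi * (t[inside] - start) / (end - start))
    return out


def _stride_starts(seg_start: float, seg_end: float, period: float,
                   phase: float) -> np.ndarray:
    """Stride start times ``seg_start + phase + k*period`` fully inside the segment."""
    first = seg_start + phase
    if first + period > seg_end + 1e-9:
        return np.array([])
    n = int(np.floor((seg_end - first) / period + 1e-9))
    return first + period * np.arange(n)


def _ankle_waveform(t: np.ndarray, starts: np.ndarray, period: float,
                    amp: float) -> np.ndarray:
    sig = np.zeros_like(t)
    for s0 in starts:
        lo = np.searchsorted(t, s0 - 0.01)
        hi = np.searchsorted(t, s0 + period + 0.01)
        u = t[lo:hi] - s0
        sig[lo:hi] += _half_sine(u, _TO_START * period, _TO_END * period,
                                 -_TO_DEPTH * amp)
        sig[lo:hi] += _half_sine(u, _MS_START * period, _MS_END * period, amp)
        sig[lo:hi] += _half_sine(u, _PH_START * period, _PH_END * period,
                                 -_PH_DEPTH * amp)
    return sig


def _bilinear_pressures(cop_x: np.ndarray, cop_y: np.ndarray,
                        force: np.ndarray) -> np.ndarray:
    """Distribute total force over the 4x4 grid so the pressure-weighted
    centroid equals (cop_x, cop_y) exactly (bilinear weights, device frame)."""
    grid = INSOLE_GRID
    step = grid[1] - grid[0]
    cx = np.clip(cop_x, grid[0], grid[-1])
    cy = np.clip(cop_y, grid[0], grid[-1])
    ix = np.clip(np.searchsorted(grid, cx, side="right") - 1, 0, 2)
    iy = np.clip(np.searchsorted(grid, cy, side="right") - 1, 0, 2)
    fx = (cx - grid[ix]) / step
    fy = (cy - grid[iy]) / step
    n = cx.size
    press = np.zeros((n, 16))
    rows = np.arange(n)
    for dx, wx in ((0, 1 - fx), (1, fx)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            press[rows, 4 * (iy + dy) + (ix + dx)] += force * wx * wy
    return press


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def simulate_trial(config: SimConfig, condition: str) -> Trial:
    """Generate one trial of the given adaptation condition.

    Returns a :class:`Trial` bundling the chest IMU, both ankle IMUs and
    both insole traces together with the exact :class:`GroundTruth`.
    """
    config.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    dt = 1.0 / fs
    n = int(round(config.total_duration_s * fs)) + 1
    t = np.arange(n) * dt
    period = 1.0 / config.cadence_hz
    segments = config.segment_bounds()
    amp = config.stride_peak_deg_s
    noise = config.noise_sd

    # --- per-foot stride events -----------------------------------------
    phases = {"left": 0.0, "right": period / 2.0}
    starts: dict[str, np.ndarray] = {}
    events: dict[str, dict[str, np.ndarray]] = {}
    for foot, ph in phases.items():
        s_all = np.concatenate(
            [_stride_starts(a, b, period, ph) for a, b in segments]
        ) if segments else np.array([])
        starts[foot] = s_all
        events[foot] = {
            "toeoff": s_all + TOEOFF_FRAC * period,
            "midswing": s_all + MIDSWING_FRAC * period,
            "heelstrike": s_all + HEELSTRIKE_FRAC * period,
        }

    # --- chest yaw: drift + integer-cycle twist oscillation -------------
    drift = config.drift_deg_per_s[condition]
    yaw = np.zeros(n)
    yaw_rate = np.zeros(n)
    slopes = []
    yaw_level = 0.0
    for a, b in segments:
        d = b - a
        rate = drift
        if config.drift_decay_tau_s:
            rate = drift * np.exp(-(a - config.walk_start_s) / config.drift_decay_tau_s)
        k = max(1, int(round(config.yaw_osc_freq_hz * d)))
        omega = 2.0 * np.pi * k / d
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        seg_t = t[i0:i1 + 1] - a
        yaw[i0:i1 + 1] = yaw_level + rate * seg_t + \
            config.yaw_osc_amp_deg * (np.cos(omega * seg_t) - 1.0)
        yaw_rate[i0:i1 + 1] = rate - config.yaw_osc_amp_deg * omega * np.sin(omega * seg_t)
        yaw_level += rate * d
        yaw[i1 + 1:] = yaw_level
        slopes.append(float(rate))

    # --- traces ----------------------------------------------------------
    def trace(channels: dict[str, np.ndarray], units: dict[str, str],
              device: str, location: str, clock_offset: float = 0.0) -> SensorTrace:
        return SensorTrace(
            timestamps=t + clock_offset,
            channels=channels,
            units=units,
            device_id=device,
            body_location=location,
        )

    gsd, asd, psd = noise["gyro"], noise["accel"], noise["pressure"]

    chest = trace(
        {
            "gyro_x": rng.normal(0.0, gsd, n),
            "gyro_y": rng.normal(0.0, gsd, n),
            "gyro_z": yaw_rate + rng.normal(0.0, gsd, n),
            "accel_x": rng.normal(0.0, asd, n),
            "accel_y": rng.normal(0.0, asd, n),
            "accel_z": GRAVITY + rng.normal(0.0, asd, n),
        },
        {"gyro_x": "deg/s", "gyro_y": "deg/s", "gyro_z": "deg/s",
         "accel_x": "m/s^2", "accel_y": "m/s^2", "accel_z": "m/s^2"},
        "imu-chest", "chest",
    )

    walking = np.zeros(n, dtype=bool)
    for a, b in segments:
        walking[int(round(a * fs)):int(round(b * fs)) + 1] = True
    wobble = config.accel_ml_amp * np.sin(2 * np.pi * 2 * config.cadence_hz * t) * walking

    slap_idx = int(round(config.slap_time_s * fs))
    slap = np.zeros(n)
    slap_amp = 10.0 * config.accel_ml_amp
    slap[slap_idx] = slap_amp
    if slap_idx > 0:
        slap[slap_idx - 1] = 0.5 * slap_amp
    if slap_idx + 1 < n:
        slap[slap_idx + 1] = 0.5 * slap_amp

    ankles = {}
    for foot in ("left", "right"):
        gyro_sag = _ankle_waveform(t, starts[foot], period, amp)
        accel_ml = wobble + (slap if foot == "left" else 0.0)
        ankles[foot] = trace(
            {
                "gyro_sag": gyro_sag + rng.normal(0.0, gsd, n),
                "accel_ml": accel_ml + rng.normal(0.0, asd, n),
            },
            {"gyro_sag": "deg/s", "accel_ml": "m/s^2"},
            f"imu-ankle-{foot}", f"ankle_{foot}",
        )

    # --- insoles ----------------------------------------------------------
    cop_off = config.cop_offset[condition]
    cop_lm_anat = {"left": config.cop_base_lm + cop_off / 2.0,
                   "right": config.cop_base_lm - cop_off / 2.0}
    insoles = {}
    for foot in ("left", "right"):
        force = np.zeros(n)
        cop_x = np.zeros(n)
        s_all = starts[foot]
        trial_end = t[-1]
        for s0 in s_all:
            a = s0 + HEELSTRIKE_FRAC * period
            b = min(s0 + _STANCE_END_FRAC * period, trial_end)
            i0, i1 = int(np.ceil(a * fs)), int(np.floor(b * fs))
            v = (t[i0:i1 + 1] - a) / (b - a)
            force[i0:i1 + 1] = 30.0 * np.sin(np.pi * v)
            cop_x[i0:i1 + 1] = -0.3 + 0.6 * v          # heel -> toe ramp
        # device frame: the right insole's lateral axis is mirrored
        y_dev = cop_lm_anat[foot] if foot == "left" else -cop_lm_anat[foot]
        press = _bilinear_pressures(cop_x, np.full(n, y_dev), force)
        press += rng.normal(0.0, psd, press.shape)
        np.clip(press, 0.0, None, out=press)
        channels = {f"p{i:02d}": press[:, i] for i in range(16)}
        channels["gyro_sag"] = _ankle_waveform(t, s_all, period, amp) \
            + rng.normal(0.0, gsd, n)
        channels["accel_ml"] = wobble + (slap if foot == "left" else 0.0) \
            + rng.normal(0.0, asd, n)
        units = {f"p{i:02d}": "norm" for i in range(16)}
        units.update({"gyro_sag": "deg/s", "accel_ml": "m/s^2"})
        insoles[foot] = trace(channels, units, f"insole-{foot}", f"foot_{foot}",
                              clock_offset=config.insole_clock_offset_s)

    all_traces = [chest, ankles["left"], ankles["right"],
                  insoles["left"], insoles["right"]]
    for start_s, length_s in config.missing_gap_spec:
        i0 = int(round(start_s * fs))
        i1 = min(n, i0 + int(round(length_s * fs)))
        for tr in all_traces:
            tr.missing_mask[i0:i1] = True
            for sig in tr.channels.values():
                sig[i0:i1] = np.nan

    truth = GroundTruth(
        event_times=events,
        segment_bounds=segments,
        true_yaw_slope_per_ws=slopes,
        true_cop_lm=cop_lm_anat,
        true_cop_sym=cop_lm_anat["left"] - cop_lm_anat["right"],
        slap_time_s=config.slap_time_s,
        insole_clock_offset_s=config.insole_clock_offset_s,
    )
    truth.validate()
    return Trial(chest, ankles["left"], ankles["right"],
                 insoles["left"], insoles["right"], truth, condition)


def simulate_study(
    config: SimConfig,
    n_subjects: int = 25,
    n_reps: int = 3,
    between_subject_sd: float = 0.3,
    seed: int | None = None,
) -> list[StudyTrial]:
    """Generate a repeated-measures study: baseline runs first, then the
    three adaptation conditions in randomized order, ``n_reps`` runs each.

    Each subject receives a persistent heading bias (drawn once, SD
    ``between_subject_sd`` deg/s) added to every condition's drift rate,
    emulating idiosyncratic veering.  Fully reproducible from the seed.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_reps < 1:
        raise ValueError("need at least 1 repetition")
    root = np.random.default_rng(config.seed if seed is None else seed)
    out: list[StudyTrial] = []
    for s in range(n_subjects):
        pid = f"P{s + 1:02d}"
        bias = root.normal(0.0, between_subject_sd) if between_subject_sd > 0 else 0.0
        drift = {c: v + bias for c, v in config.drift_deg_per_s.items()}
        adaptation = [(c, r) for c in ("supine", "RED", "LED") for r in range(1, n_reps + 1)]
        root.shuffle(adaptation)
        schedule = [("baseline", r) for r in range(1, n_reps + 1)] + adaptation
        for cond, rep in schedule:
            child = int(root.integers(0, 2**31 - 1))
            cfg = replace(config, seed=child, drift_deg_per_s=drift)
            out.append(StudyTrial(pid, cond, rep, simulate_trial(cfg, cond)))
    return out


# ---------------------------------------------------------------------------
# measure-level study simulation (for inference calibration)
# ---------------------------------------------------------------------------

def simulate_measure_table(
    seed: int,
    n_subjects: int = 25,
    n_reps: int = 3,
    condition_effects: dict[str, float] | None = None,
    ws_decay: tuple[float, float, float] = (1.0, 0.6, 0.36),
    subject_sd: float = 0.2,
    subject_ws_sd: float = 0.0,
    residual_sd: float = 0.2,
):
    """Simulate a long-format study table of one gait measure directly.

    ``value = effect[condition] * ws_decay[ws-1] + b_subject (+ b_subject_ws)
    + noise``.  This is the study-design layer of the generator, used to
    calibrate the mixed-model inference at realistic replicate counts
    without re-synthesizing 100 Hz sensor traces.
    """
    import pandas as pd

    if condition_effects is None:
        condition_effects = _default_drift()
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        pid = f"P{s + 1:02d}"
        b = rng.normal(0.0, subject_sd)
        b_ws = rng.normal(0.0, subject_ws_sd, 3) if subject_ws_sd > 0 else np.zeros(3)
        for cond in CONDITIONS:
            for rep in range(1, n_reps + 1):
                for ws in (1, 2, 3):
                    val = (condition_effects[cond] * ws_decay[ws - 1]
                           + b + b_ws[ws - 1] + rng.normal(0.0, residual_sd))
                    rows.append((pid, cond, rep, ws, val))
    return pd.DataFrame(
        rows, columns=["participant", "trial", "repetition", "walkingSegment", "value"]
    )


def simulate_paired_measure_tables(
    seed: int,
    n_subjects: int = 25,
    n_reps: int = 3,
    condition_effects: dict[str, float] | None = None,
    cop_gain: float = -0.08,
    cop_subject_sd: float = 0.02,
    cop_condition_sd: float = 0.03,
    cop_residual_sd: float = 0.01,
    **kwargs,
):
    """Paired yaw-slope and CoP-symmetry tables with opposing signs.

    The CoP symmetry of a subject-condition cell is constructed as
    ``cop_gain * (condition effect + subject bias) + noise``, so that a
    leftward heading drift co-occurs with a leftward weight shift
    (negative symmetry), giving a negative yaw-CoP correlation by
    construction.
    """
    import pandas as pd

    if condition_effects is None:
        condition_effects = _default_drift()
    yaw = simulate_measure_table(
        seed, n_subjects=n_subjects, n_reps=n_reps,
        condition_effects=condition_effects, **kwargs,
    )
    rng = np.random.default_rng(seed + 1)
    rows = []
    for s in range(n_subjects):
        pid = f"P{s + 1:02d}"
        b = rng.normal(0.0, cop_subject_sd)
        for cond in CONDITIONS:
            cell = cop_gain * condition_effects[cond] + b \
                + rng.normal(0.0, cop_condition_sd)
            for rep in range(1, n_reps + 1):
                for ws in (1, 2, 3):
                    rows.append((pid, cond, rep, ws,
                                 cell + rng.normal(0.0, cop_residual_sd)))
    cop = pd.DataFrame(
        rows, columns=["participant", "trial", "repetition", "walkingSegment", "value"]
    )
    return yaw, cop
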