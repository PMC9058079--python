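"""File formats, configuration and end-to-end orchestration.

Traces travel as plain CSV (no public schema exists for either vendor's
binary export): a small ``#``-prefixed metadata header (device, body
location, channel units as JSON) followed by a ``time_s`` column and one
named column per channel; empty cells are missing samples.  Studies are
described by a JSON manifest listing each trial's files, and ground-truth
sidecars (when present) are JSON.

``run_pipeline`` executes the full chain - preprocessing/synchronization,
walking-segment separation, orientation fusion with per-segment yaw
regression, per-step/per-segment CoP with the left-right symmetry, and
the mixed-model condition analysis - and writes a reproducible report.
Every excluded trial, segment or step is logged with its reason; nothing
is dropped silently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cop as cop_mod
from . import events as ev_mod
from . import orientation as ori_mod
from . import stats as stats_mod
from .preprocess import SensorTrace, SyncNotFoundError, detect_slap, fill_gaps, synchronize
from .synthgait import SimConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = [
    "TraceFormatError",
    "MissingChannelError",
    "NonMonotonicTimeError",
    "UnitMismatchError",
    "PipelineConfig",
    "TrialManifest",
    "read_trace",
    "write_trace",
    "process_trial",
    "run_pipeline",
    "make_fixture",
]


class TraceFormatError(ValueError):
    """Base class for trace-file validation failures."""


class MissingChannelError(TraceFormatError):
    """A channel required by the device role is absent."""


class NonMonotonicTimeError(TraceFormatError):
    """Timestamps are not strictly increasing."""


class UnitMismatchError(TraceFormatError):
    """A channel's declared unit conflicts with the role schema."""


ROLE_SCHEMAS: dict[str, dict[str, str]] = {
    "chest": {
        "gyro_x": "deg/s", "gyro_y": "deg/s", "gyro_z": "deg/s",
        "accel_x": "m/s^2", "accel_y": "m/s^2", "accel_z": "m/s^2",
    },
    "ankle": {"gyro_sag": "deg/s", "accel_ml": "m/s^2"},
    "insole": {
        **{f"p{i:02d}": "norm" for i in range(16)},
        "gyro_sag": "deg/s", "accel_ml": "m/s^2",
    },
}

TRIAL_FILES = ("chest", "ankle_left", "ankle_right", "insole_left", "insole_right")


@dataclass
class PipelineConfig:
    """Every tunable of the processing chain, with the package defaults."""

    seed: int = 0
    slap_search_s: float = 15.0          # slap searched in the first N seconds
    slap_threshold: float | None = None  # None -> robust 10xMAD default
    max_gap_s: float = 0.2
    segment_gap_s: float = 2.0
    min_strides_per_segment: int = 3
    max_ws: int = 3                      # walking segments entering the stats
    tilt_tau_s: float = 1.0
    lowpass_cutoff_hz: float = 12.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class TrialManifest:
    participant: str
    condition: str
    repetition: int
    paths: dict[str, str]            # role -> file path
    truth_path: str | None = None


# ---------------------------------------------------------------------------
# trace CSV dialect
# ---------------------------------------------------------------------------

def write_trace(trace: SensorTrace, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# tiltwalk-trace v1\n")
        fh.write(f"# device_id: {trace.device_id}\n")
        fh.write(f"# body_location: {trace.body_location}\n")
        fh.write(f"# units: {json.dumps(trace.units, sort_keys=True)}\n")
        cols = list(trace.channels)
        fh.write("time_s," + ",".join(cols) + "\n")
        data = np.column_stack([trace.timestamps] +
                               [trace.channels[c] for c in cols])
        miss = trace.missing_mask
        for i in range(data.shape[0]):
            row = [f"{data[i, 0]:.6f}"]
            if miss[i]:
                row += [""] * len(cols)
            else:
                row += [f"{v:.6f}" for v in data[i, 1:]]
            fh.write(",".join(row) + "\n")


def read_trace(path: str | Path, role: str) -> SensorTrace:
    """Read and validate a trace CSV against its device-role schema.

    Raises :class:`MissingChannelError`, :class:`NonMonotonicTimeError`
    or :class:`UnitMismatchError` as distinct, named failures.
    """
    if role not in ROLE_SCHEMAS:
        raise ValueError(f"unknown role {role!r}")
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    units = json.loads(meta.get("units", "{}"))
    df = pd.read_csv(path, skiprows=n_header)
    if "time_s" not in df.columns:
        raise TraceFormatError(f"{path}: no time_s column")
    schema = ROLE_SCHEMAS[role]
    missing = set(schema) - set(df.columns)
    if missing:
        raise MissingChannelError(f"{path}: missing channels {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise NonMonotonicTimeError(f"{path}: non-monotonic time")
    for ch, expected in schema.items():
        declared = units.get(ch)
        if declared is not None and declared != expected:
            raise UnitMismatchError(
                f"{path}: channel {ch} declared {declared!r}, expected {expected!r}"
            )
    channels = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time_s"}
    mask = np.zeros(t.size, dtype=bool)
    for sig in channels.values():
        mask |= np.isnan(sig)
    return SensorTrace(
        timestamps=t, channels=channels,
        units={c: units.get(c, ROLE_SCHEMAS[role].get(c, "")) for c in channels},
        missing_mask=mask,
        device_id=meta.get("device_id", ""),
        body_location=meta.get("body_location", ""),
    )


def read_manifest(path: str | Path) -> list[TrialManifest]:
    raw = json.loads(Path(path).read_text())
    base = Path(path).parent
    out = []
    seen = set()
    for item in raw["trials"]:
        key = (item["participant"], item["condition"], item["repetition"])
        if key in seen:
            raise ValueError(f"duplicate trial key {key}")
        seen.add(key)
        paths = {k: str(base / v) for k, v in item["paths"].items()}
        truth = item.get("truth")
        out.append(TrialManifest(
            participant=item["participant"], condition=item["condition"],
            repetition=int(item["repetition"]), paths=paths,
            truth_path=str(base / truth) if truth else None,
        ))
    return out


# ---------------------------------------------------------------------------
# single-trial processing
# ---------------------------------------------------------------------------

@dataclass
class TrialResult:
    yaw_slopes: dict[int, float] = field(default_factory=dict)    # ws -> deg/s
    cop_syms: dict[int, float] = field(default_factory=dict)      # ws -> norm units
    n_ws_imu: int = 0
    n_ws_insole: int = 0
    sync_offset_s: float | None = None
    notes: list[str] = field(default_factory=list)


def _foot_events(trace: SensorTrace, foot: str, cfg: PipelineConfig) -> ev_mod.GaitEvents:
    fs = trace.sample_rate_hz
    smoothed = ev_mod.lowpass(np.nan_to_num(trace.channels["gyro_sag"]),
                              fs, cutoff_hz=cfg.lowpass_cutoff_hz)
    return ev_mod.extract_gait_events(smoothed, fs, foot, t0=trace.timestamps[0])


def process_trial(traces: dict[str, SensorTrace],
                  cfg: PipelineConfig | None = None) -> TrialResult:
    """Run one trial through sync, events, yaw regression and CoP.

    ``traces`` maps roles (chest, ankle_left/right, insole_left/right) to
    traces; insoles may be absent, in which case only the yaw measure is
    produced and the omission is noted.

    Raises
    ------
    SyncNotFoundError
        If the slap cannot be found on the IMU system: the trial is
        unusable.
    """
    cfg = cfg or PipelineConfig()
    res = TrialResult()
    traces = {k: fill_gaps(v, cfg.max_gap_s) for k, v in traces.items()}
    chest = traces["chest"]
    ankle_l, ankle_r = traces["ankle_left"], traces["ankle_right"]
    fs = chest.sample_rate_hz

    # --- synchronization (slap on the left leg in both systems) ---------
    t0 = ankle_l.timestamps[0]
    slap_imu = detect_slap(
        ankle_l.channels["accel_ml"], fs, threshold=cfg.slap_threshold,
        search_window_s=(t0, t0 + cfg.slap_search_s), t0=t0,
    )
    have_insoles = "insole_left" in traces and "insole_right" in traces
    if have_insoles:
        ins_l = traces["insole_left"]
        try:
            slap_ins = detect_slap(
                ins_l.channels["accel_ml"], ins_l.sample_rate_hz,
                threshold=cfg.slap_threshold,
                search_window_s=(ins_l.timestamps[0],
                                 ins_l.timestamps[0] + cfg.slap_search_s),
                t0=ins_l.timestamps[0],
            )
            for key in ("insole_left", "insole_right"):
                _, shifted = synchronize(ankle_l, traces[key], slap_imu, slap_ins)
                traces[key] = shifted
            res.sync_offset_s = slap_imu - slap_ins
        except SyncNotFoundError:
            have_insoles = False
            res.notes.append("insole sync not found; CoP measures skipped")
    else:
        res.notes.append("insole data missing; CoP measures skipped")

    # --- IMU system: events, segments, yaw slope ------------------------
    ev_l = _foot_events(ankle_l, "left", cfg)
    ev_r = _foot_events(ankle_r, "right", cfg)
    segments = ev_mod.segment_walking(
        ev_l, ev_r, min_gap_s=cfg.segment_gap_s,
        min_strides=cfg.min_strides_per_segment,
    )
    res.n_ws_imu = len(segments)
    ori = ori_mod.fuse(
        np.column_stack([chest.channels[f"gyro_{ax}"] for ax in "xyz"]),
        np.column_stack([chest.channels[f"accel_{ax}"] for ax in "xyz"]),
        fs, tilt_tau_s=cfg.tilt_tau_s,
    )
    for seg in segments[:cfg.max_ws]:
        res.yaw_slopes[seg.index] = ori_mod.yaw_slope(ori, seg).slope_deg_per_s

    # --- insole system: events, segments, CoP symmetry ------------------
    if have_insoles:
        ins = {"left": traces["insole_left"], "right": traces["insole_right"]}
        ins_ev = {f: _foot_events(ins[f], f, cfg) for f in ("left", "right")}
        ins_segments = ev_mod.segment_walking(
            ins_ev["left"], ins_ev["right"], min_gap_s=cfg.segment_gap_s,
            min_strides=cfg.min_strides_per_segment,
        )
        res.n_ws_insole = len(ins_segments)
        series = {f: cop_mod.cop_series(ins[f], f) for f in ("left", "right")}
        thresh = {f: cop_mod.contact_threshold_for(series[f]) for f in ("left", "right")}
        for seg in ins_segments[:cfg.max_ws]:
            ws_means = {}
            for foot in ("left", "right"):
                ev = ins_ev[foot]
                ids = seg.strides.get(foot, np.array([], dtype=int))
                steps = []
                windows = cop_mod.stance_windows(ev)
                for sid in ids:
                    if sid < len(windows):
                        val = cop_mod.step_cop(series[foot], windows[sid], thresh[foot])
                        if val is not None:
                            steps.append(val)
                m = cop_mod.ws_cop(steps, seg, foot)
                ws_means[foot] = None if m is None else m.mean_lm
            sym = cop_mod.cop_sym(ws_means["left"], ws_means["right"])
            if sym is None:
                res.notes.append(f"WS{seg.index}: CoP missing on one foot")
            else:
                res.cop_syms[seg.index] = sym
    return res


# ---------------------------------------------------------------------------
# study pipeline
# ---------------------------------------------------------------------------

def run_pipeline(manifest: str | Path | list[TrialManifest],
                 cfg: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Process every trial of a study and run the condition analysis.

    Returns the report as a dict; when ``out_dir`` is given, also writes
    ``study_table.csv``, ``emm.csv``, ``contrasts.csv``,
    ``assumptions.json``, ``correlation.json``, ``exclusions.csv`` and
    ``summary.json`` there.
    """
    cfg = cfg or PipelineConfig()
    if not isinstance(manifest, list):
        manifest = read_manifest(manifest)

    rows = []
    exclusions = []
    n_ws_counts = []
    for tm in manifest:
        traces = {}
        try:
            for role_key, path in sorted(tm.paths.items()):
                role = "chest" if role_key == "chest" else role_key.split("_")[0]
                if Path(path).exists():
                    traces[role_key] = read_trace(path, role)
                elif role_key.startswith("insole"):
                    exclusions.append((tm.participant, tm.condition, tm.repetition,
                                       f"missing file for {role_key}: CoP excluded"))
                else:
                    raise FileNotFoundError(path)
            result = process_trial(traces, cfg)
        except SyncNotFoundError as exc:
            exclusions.append((tm.participant, tm.condition, tm.repetition,
                               f"sync failed: {exc}"))
            continue
        except (TraceFormatError, FileNotFoundError) as exc:
            exclusions.append((tm.participant, tm.condition, tm.repetition,
                               f"unreadable trial: {exc}"))
            continue
        if result.n_ws_imu == 0:
            exclusions.append((tm.participant, tm.condition, tm.repetition,
                               "no walking segments detected"))
            continue
        for note in result.notes:
            exclusions.append((tm.participant, tm.condition, tm.repetition, note))
        n_ws_counts.append(result.n_ws_imu)
        for ws, slope in result.yaw_slopes.items():
            rows.append((tm.participant, tm.condition, tm.repetition, ws,
                         "yaw_slope", slope))
        for ws, sym in result.cop_syms.items():
            rows.append((tm.participant, tm.condition, tm.repetition, ws,
                         "cop_sym", sym))

    table = pd.DataFrame(
        rows, columns=["participant", "trial", "repetition",
                       "walkingSegment", "measure", "value"],
    )
    report: dict = {
        "n_trials": len(manifest),
        "n_trials_processed": len(n_ws_counts),
        "mean_ws_per_trial": float(np.mean(n_ws_counts)) if n_ws_counts else 0.0,
        "sd_ws_per_trial": float(np.std(n_ws_counts)) if n_ws_counts else 0.0,
        "exclusions": exclusions,
        "df_method": stats_mod.DF_METHOD,
        "measures": {},
    }

    corr_inputs = {}
    for measure in ("yaw_slope", "cop_sym"):
        sub = table[table["measure"] == measure].drop(columns="measure")
        m_report: dict = {"n_obs": int(len(sub))}
        if sub.empty or sub["trial"].nunique() < 2:
            report["measures"][measure] = m_report
            continue
        filtered = stats_mod.remove_extremes_table(sub)
        m_report["n_extreme_removed"] = int(len(sub) - len(filtered))
        try:
            m_report["assumptions"] = stats_mod.assumption_tests(filtered)
        except ValueError as exc:
            m_report["assumptions"] = {"error": str(exc)}
        try:
            fit = stats_mod.fit_lme(filtered)
            m_report["singular_fit"] = fit.singular
            m_report["emm"] = fit.emm_table().to_dict("records")
            contrasts = []
            for ws in fit.ws_levels:
                for c in stats_mod.pairwise_emm(fit, ws):
                    contrasts.append({
                        "measure": measure, "ws": ws,
                        "pair": f"{c.pair[0]} - {c.pair[1]}",
                        "estimate": c.estimate, "se": c.se,
                        "p_unadjusted": c.p_unadjusted,
                        "p_adjusted": c.p_adjusted, "stars": c.stars,
                    })
            m_report["contrasts"] = contrasts
        except Exception as exc:   # degenerate tables on tiny fixtures
            logger.warning("mixed model failed for %s: %s", measure, exc)
            m_report["model_error"] = str(exc)
        report["measures"][measure] = m_report
        corr_inputs[measure] = sub

    if len(corr_inputs) == 2:
        try:
            yaw_bc = stats_mod.baseline_correct(corr_inputs["yaw_slope"])
            cop_bc = stats_mod.baseline_correct(corr_inputs["cop_sym"])
            merged = yaw_bc.merge(cop_bc, on=["participant", "trial"],
                                  suffixes=("_yaw", "_cop"))
            r, p, n = stats_mod.correlate(merged["corrected_yaw"],
                                          merged["corrected_cop"])
            report["correlation"] = {"r": r, "p": p, "n": n}
        except ValueError as exc:
            report["correlation"] = {"error": str(exc)}

    if out_dir is not None:
        _write_report(report, table, Path(out_dir))
    return report


def _write_report(report: dict, table: pd.DataFrame, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / "study_table.csv", index=False, float_format="%.8f")
    contrasts = []
    emms = []
    for measure, m in report["measures"].items():
        contrasts.extend(m.get("contrasts", []))
        for row in m.get("emm", []):
            emms.append({"measure": measure, **row})
    pd.DataFrame(contrasts).to_csv(out_dir / "contrasts.csv", index=False,
                                   float_format="%.8f")
    pd.DataFrame(emms).to_csv(out_dir / "emm.csv", index=False, float_format="%.8f")
    pd.DataFrame(report["exclusions"],
                 columns=["participant", "trial", "repetition", "reason"]
                 ).to_csv(out_dir / "exclusions.csv", index=False)
    (out_dir / "assumptions.json").write_text(json.dumps(
        {m: r.get("assumptions") for m, r in report["measures"].items()},
        indent=1, sort_keys=True, default=float))
    (out_dir / "correlation.json").write_text(json.dumps(
        report.get("correlation", {}), indent=1, sort_keys=True, default=float))
    summary = {k: v for k, v in report.items() if k not in ("measures", "exclusions")}
    summary["measures"] = {
        m: {k: v for k, v in r.items() if k in
            ("n_obs", "n_extreme_removed", "singular_fit", "model_error")}
        for m, r in report["measures"].items()
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1,
                                                     sort_keys=True, default=float))


# ---------------------------------------------------------------------------
# bundled synthetic fixture
# ---------------------------------------------------------------------------

def make_fixture(out_dir: str | Path, seed: int,
                 n_subjects: int = 4, n_reps: int = 2,
                 walk_duration_s: float = 60.0, n_segments: int = 4,
                 **config_overrides) -> Path:
    """Write a small synthetic study to disk and return the manifest path.

    Default shape: 4 subjects x 4 conditions x 2 repetitions of 60 s
    walks - large enough to exercise every pipeline stage, small enough
    for tests and docs.  Fixed seed -> identical bytes on re-run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = SimConfig(seed=seed, walk_duration_s=walk_duration_s,
                    n_segments=n_segments, **config_overrides)
    study = simulate_study(sim, n_subjects=n_subjects, n_reps=n_reps, seed=seed)
    items = []
    for st in study:
        name = f"{st.participant}_{st.condition}_r{st.repetition}"
        tdir = out_dir / name
        tdir.mkdir(exist_ok=True)
        paths = {}
        for role, trace in st.trial.traces.items():
            write_trace(trace, tdir / f"{role}.csv")
            paths[role] = f"{name}/{role}.csv"
        (tdir / "truth.json").write_text(st.trial.truth.to_json())
        items.append({
            "participant": st.participant, "condition": st.condition,
            "repetition": st.repetition, "paths": paths,
            "truth": f"{name}/truth.json",
        })
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"trials": items}, indent=1, sort_keys=True))
    return manifest_path
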