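"""Readers, writers, run configuration and the analysis pipeline.

Tracked midlines arrive either as pose-estimation CSV (the three-header-
row dialect: scorer / bodyparts / coords with x, y and a per-point
likelihood column) or as plain TSV (time, x1, y1, ..., x11, y11).
Low-likelihood samples are masked and linearly interpolated across gaps of
up to three frames; longer gaps stay missing and are excluded downstream.
Extracellular-like traces are CSV/TSV (time plus one column per channel)
with a JSON sidecar carrying per-channel side and rostrocaudal position.

``run_pipeline`` ties the stages together from a single validated
configuration mapping and writes a directory bundle: report.json, tidy
CSVs and a resolved_config.yaml echoing every parameter actually used.
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

from . import ephys, kinematics, surrogate, synthetic

log = logging.getLogger("tadstruggle")

__all__ = [
    "RunConfig",
    "read_pose_csv",
    "read_body_tsv",
    "write_body_tsv",
    "write_angles_csv",
    "read_angles_csv",
    "read_traces",
    "write_traces",
    "load_config",
    "run_pipeline",
]

DEFAULT_POINT_NAMES = tuple(f"p{i}" for i in range(1, 12))


def _interpolate_short_gaps(arr: np.ndarray, max_gap: int = 3) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap; leave longer runs."""
    arr = arr.copy()
    n = arr.shape[0]
    for col in range(arr.shape[1]):
        x = arr[:, col]
        bad = ~np.isfinite(x)
        if not bad.any() or bad.all():
            continue
        i = 0
        idx = np.arange(n)
        good = ~bad
        while i < n:
            if bad[i]:
                j = i
                while j < n and bad[j]:
                    j += 1
                interior = i > 0 and j < n
                if interior and (j - i) <= max_gap:
                    x[i:j] = np.interp(idx[i:j], idx[good], x[good])
                i = j
            else:
                i += 1
        arr[:, col] = x
    return arr


def read_pose_csv(path, dialect: str = "auto",
                  point_names=DEFAULT_POINT_NAMES,
                  frame_rate: float = 240.0,
                  likelihood_cutoff: float = 0.9,
                  body_length: float | None = None,
                  ) -> kinematics.TrackedBody:
    """Read tracked midline coordinates.

    dialect "three_header_row": pose-estimation CSV with scorer /
    bodyparts / coords header rows and x, y, likelihood per point; points
    are resolved by body-part name, so column order is irrelevant.
    dialect "plain_tsv": columns time, x1, y1, ..., x11, y11.
    "auto" sniffs the first line.
    """
    path = Path(path)
    if dialect == "auto":
        first = path.open().readline()
        dialect = ("three_header_row" if first.lower().startswith("scorer")
                   else "plain_tsv")
    if dialect == "plain_tsv":
        return read_body_tsv(path, frame_rate=frame_rate,
                             body_length=body_length)
    if dialect != "three_header_row":
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    parts = df.columns.get_level_values(1)
    missing = [p for p in point_names if p not in set(parts)]
    if missing:
        raise ValueError(f"body parts missing from {path.name}: {missing}")
    n = len(df)
    pts = np.full((n, len(point_names), 2), np.nan)
    for k, name in enumerate(point_names):
        sub = df.xs(name, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        try:
            x = sub["x"].to_numpy(dtype=float)
            y = sub["y"].to_numpy(dtype=float)
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"non-numeric or missing x/y for body part {name!r}") from exc
        if "likelihood" in sub.columns:
            ok = sub["likelihood"].to_numpy(dtype=float) >= likelihood_cutoff
            x = np.where(ok, x, np.nan)
            y = np.where(ok, y, np.nan)
        pts[:, k, 0] = x
        pts[:, k, 1] = y
    flat = _interpolate_short_gaps(pts.reshape(n, -1)).reshape(pts.shape)
    times = np.arange(n) / frame_rate
    return kinematics.TrackedBody.from_points(times, flat, frame_rate,
                                              body_length)


def read_body_tsv(path, frame_rate: float | None = None,
                  body_length: float | None = None) -> kinematics.TrackedBody:
    """Plain dialect: whitespace/tab separated time, x1, y1, ..., x11, y11."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] != 1 + 2 * kinematics.N_POINTS:
        raise ValueError("plain midline file needs 1 time + 22 coordinate "
                         f"columns, found {df.shape[1]}")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    pts = df.iloc[:, 1:].to_numpy(dtype=float).reshape(
        len(df), kinematics.N_POINTS, 2)
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(times)))
    return kinematics.TrackedBody.from_points(times, pts, frame_rate,
                                              body_length)


def write_body_tsv(body: kinematics.TrackedBody, path) -> None:
    cols = {"time": body.times}
    for i in range(kinematics.N_POINTS):
        cols[f"x{i + 1}"] = body.points[:, i, 0]
        cols[f"y{i + 1}"] = body.points[:, i, 1]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                              float_format="%.6f")


def write_angles_csv(angle_set: kinematics.AngleSet, path) -> None:
    """Angle traces as CSV: time_s, alpha1..alpha9 (rad), sum (rad)."""
    cols = {"time_s": angle_set.times}
    for j in range(kinematics.N_ANGLES):
        cols[f"alpha{j + 1}_rad"] = angle_set.angles[:, j]
    cols["sum_rad"] = angle_set.sum_trace
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9f")


def read_angles_csv(path, frame_rate: float | None = None,
                    body_length: float = 5.0) -> kinematics.AngleSet:
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy(dtype=float)
    angles = df[[f"alpha{j + 1}_rad"
                 for j in range(kinematics.N_ANGLES)]].to_numpy(dtype=float)
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(times)))
    positions = (np.arange(1, kinematics.N_ANGLES + 1)
                 / (kinematics.N_POINTS - 1) * body_length)
    return kinematics.AngleSet(times=times, angles=angles,
                               sum_trace=angles.sum(axis=1),
                               vertex_positions=positions,
                               frame_rate=frame_rate)


def write_traces(traces: list[ephys.RhythmTrace], path) -> None:
    """CSV of time + one column per channel with a JSON metadata sidecar."""
    path = Path(path)
    n = max(t.samples.size for t in traces)
    fs = traces[0].sampling_rate
    cols = {"time_s": np.arange(n) / fs}
    meta = {"sampling_rate": fs, "channels": []}
    for i, t in enumerate(traces):
        name = t.name or f"ch{i}"
        cols[name] = np.pad(t.samples, (0, n - t.samples.size),
                            constant_values=np.nan)
        meta["channels"].append({"name": name, "side": t.side,
                                 "position_mm": t.position})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.4f")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1))


def read_traces(path, meta_path=None) -> list[ephys.RhythmTrace]:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(
        path.suffix + ".json")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(path, sep=None, engine="python")
    out = []
    for ch in meta["channels"]:
        samples = df[ch["name"]].to_numpy(dtype=float)
        samples = samples[np.isfinite(samples)]
        out.append(ephys.RhythmTrace(
            samples=samples, sampling_rate=float(meta["sampling_rate"]),
            side=ch["side"], position=float(ch["position_mm"]),
            name=ch["name"]))
    return out


# ---------------------------------------------------------------------------
# configuration and pipeline


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "tadstruggle_out"
    log_level: str = "INFO"
    kinematics: dict = field(default_factory=dict)
    ephys: dict = field(default_factory=dict)
    surrogate: dict = field(default_factory=dict)
    forces: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path) -> RunConfig:
    path = Path(path)
    with path.open() as fh:
        data = (json.load(fh) if path.suffix == ".json"
                else yaml.safe_load(fh))
    return RunConfig.from_mapping(data or {})


def _kinematics_stage(cfg: RunConfig, out: Path) -> dict:
    params = dict(cfg.kinematics)
    src = params.pop("input", None)
    if src is None:
        raise ValueError("kinematics stage needs an 'input' midline file")
    cutoff = float(params.pop("filter_cutoff_hz", 50.0))
    after_release = bool(params.pop("after_release", False))
    body = read_pose_csv(src, dialect=params.pop("dialect", "auto"),
                         frame_rate=float(params.pop("frame_rate", 240.0)),
                         likelihood_cutoff=float(
                             params.pop("likelihood_cutoff", 0.9)))
    if params:
        raise ValueError(f"unknown kinematics parameters: {sorted(params)}")
    angles = kinematics.compute_curvature_angles(body)
    filt = kinematics.lowpass_sum(angles, cutoff=cutoff)
    log.info("kinematics: filter_cutoff_hz=%s after_release=%s",
             cutoff, after_release)
    write_angles_csv(filt, out / "angles.csv")
    cycles = kinematics.detect_half_cycles(filt.sum_trace, filt.times)
    report: dict = {
        "n_frames": body.n_frames,
        "filter_cutoff_hz": cutoff,
        "n_half_cycles": len(cycles),
    }
    if cycles:
        try:
            prop = kinematics.propagation_speed(filt)
        except ValueError:
            prop = None
        label = kinematics.classify_movement(cycles, prop,
                                             after_release=after_release)
        report.update({
            "label": label.label,
            "amplitude_rad": label.amplitude,
            "half_cycle_ms": label.half_cycle_ms,
            "propagation_speed_mm_s": None if prop is None
            else prop.speed,
            "propagation_p": None if prop is None else prop.regression_p,
            "synchronous": None if prop is None else prop.synchronous,
        })
    return report


def _ephys_stage(cfg: RunConfig, out: Path) -> dict:
    params = dict(cfg.ephys)
    src = params.pop("input", None)
    if src is None:
        raise ValueError("ephys stage needs an 'input' trace file")
    baseline = tuple(params.pop("baseline_window", (0.0, 0.05)))
    k = float(params.pop("threshold_k", 5.0))
    max_gap = float(params.pop("burst_max_gap_ms", 15.0))
    bin_width = float(params.pop("rhythm_bin_ms", 5.0))
    meta_path = params.pop("meta", None)
    if params:
        raise ValueError(f"unknown ephys parameters: {sorted(params)}")
    traces = read_traces(src, meta_path)
    log.info("ephys: threshold_k=%s burst_max_gap_ms=%s rhythm_bin_ms=%s "
             "refractory_ms=1.0 smooth_window_ms=2.5", k, max_gap, bin_width)
    report: dict = {"threshold_k": k, "burst_max_gap_ms": max_gap,
                    "rhythm_bin_ms": bin_width, "channels": []}
    processed, rows = [], []
    for tr in traces:
        p = ephys.preprocess(tr)
        processed.append(p)
        events = ephys.trigger_events(p, baseline, k=k)
        ch: dict = {"name": tr.name, "side": tr.side,
                    "position_mm": tr.position,
                    "n_events": int(events.event_times.size)}
        if events.event_times.size >= 2:
            bursts, stats = ephys.group_bursts(events, max_gap=max_gap)
            ch.update({"n_bursts": len(bursts),
                       "cycle_period_ms": stats.cycle_period,
                       "frequency_hz": stats.frequency,
                       "duty_cycle": stats.duty_cycle})
            for b in bursts:
                rows.append((tr.name, b.start, b.end, b.duration, b.n_events))
            if events.event_times.size >= 11:
                r = ephys.rhythmicity_index(events.event_times, bin_width)
                ch["rhythmicity"] = r.value
                ch["rhythmicity_flagged"] = r.flagged
        report["channels"].append(ch)
    pd.DataFrame(rows, columns=["channel", "start_s", "end_s",
                                "duration_ms", "n_events"]).to_csv(
        out / "bursts.csv", index=False)
    same_side = [p for p in processed if p.side == processed[0].side]
    if len(same_side) >= 2:
        prop = ephys.xcorr_propagation(same_side[0], same_side[1])
        report["propagation"] = {"delay_ms": prop.delay,
                                 "speed_mm_s": prop.speed,
                                 "synchronous": prop.synchronous,
                                 "defined": prop.defined}
    return report


def _surrogate_stage(cfg: RunConfig, out: Path, seed: int) -> dict:
    params = dict(cfg.surrogate)
    pattern = params.pop("pattern", "struggle")
    factory = {"struggle": surrogate.struggle_config,
               "swim": surrogate.swim_config,
               "initial_coil": surrogate.initial_coil_config}[pattern]
    reverse = bool(params.pop("reverse", False))
    config = factory(seed=int(params.pop("seed", seed)), **params)
    roster = surrogate.build_roster()
    table = (surrogate.generate_reverse(config, roster) if reverse
             else surrogate.generate(config, roster))
    table.write(out / "commands.tsv")
    log.info("surrogate: pattern=%s reverse=%s seed=%s", pattern, reverse,
             config.seed)
    return {"pattern": pattern, "reverse": reverse,
            "n_spikes": int(len(table.frame)),
            "n_neurons_per_side": roster.n_per_side}


def _forces_stage(cfg: RunConfig, out: Path) -> dict:
    from . import mechanics
    params = dict(cfg.forces)
    src = params.pop("tracked", None)
    if src is None:
        raise ValueError("forces stage needs a 'tracked' midline file")
    body_model = mechanics.BodyModel(**params.pop("body", {}))
    smooth = params.pop("smooth_cutoff_hz", None)
    if params:
        raise ValueError(f"unknown forces parameters: {sorted(params)}")
    tracked = read_pose_csv(src)
    times, endpoints = mechanics.sections_from_tracked(tracked)
    drag = mechanics.pressure_drag(body_model, times, endpoints)
    inertia = mechanics.mass_acceleration(body_model, times, endpoints,
                                          smooth_cutoff=smooth)
    drag.to_csv(out / "drag.csv", index=False)
    inertia.to_csv(out / "mass_acceleration.csv", index=False)
    log.info("forces: zeta=%s total_side_area=%s smooth_cutoff_hz=%s",
             body_model.zeta, body_model.total_side_area, smooth)
    return {"peak_drag_uN": float(np.nanmax(drag["Fmag"])),
            "peak_mass_acc_uN": float(np.nanmax(inertia["Fmag"]))}


def _synth_stage(cfg: RunConfig, out: Path, seed: int) -> dict:
    params = dict(cfg.synth)
    kind = params.pop("kind", "movement")
    if kind == "movement":
        preset = params.pop("preset", "struggling")
        spec = synthetic.movement_preset(preset,
                                         seed=int(params.pop("seed", seed)),
                                         **params)
        body, truth = synthetic.make_tracked_movement(spec)
        write_body_tsv(body, out / "body.tsv")
        (out / "ground_truth.json").write_text(json.dumps(
            {"frequency_hz": truth.frequency,
             "amplitude_rad": truth.amplitude,
             "propagation_speed_mm_s": truth.propagation_speed,
             "origin_fraction": truth.origin}, indent=1))
        return {"kind": kind, "preset": preset, "frames": body.n_frames}
    if kind == "traces":
        spec = synthetic.TraceSpec(seed=int(params.pop("seed", seed)),
                                   **params)
        traces, truth = synthetic.make_vr_traces(spec)
        write_traces(traces, out / "traces.csv")
        (out / "ground_truth.json").write_text(json.dumps(
            {"cycle_period_ms": spec.cycle_period,
             "burst_duration_ms": spec.burst_duration,
             "propagation_speed_mm_s": spec.propagation_speed,
             "event_times": [t.tolist() for t in truth.event_times]},
            indent=1))
        return {"kind": kind, "n_channels": len(traces)}
    raise ValueError(f"unknown synth kind {kind!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write the report bundle.

    Output directory receives report.json, stage CSV/TSV files and
    resolved_config.yaml.  A stage failure raises with the stage name in
    the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO))
    report: dict = {"seed": config.seed}
    stages = [("synth", _synth_stage), ("kinematics", _kinematics_stage),
              ("ephys", _ephys_stage), ("surrogate", _surrogate_stage),
              ("forces", _forces_stage)]
    ran = 0
    for name, fn in stages:
        if not getattr(config, name):
            continue
        try:
            if name in ("surrogate", "synth"):
                report[name] = fn(config, out, config.seed)
            else:
                report[name] = fn(config, out)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        ran += 1
    if ran == 0:
        raise ValueError("configuration enables no stage")
    (out / "report.json").write_text(json.dumps(report, indent=1,
                                                default=float))
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config)))
    return report
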