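"""Trial directory layout: one CSV per trace plus a JSON manifest.

Each trial is a directory ``trial_<id>/`` containing ``po2_<label>.csv`` and
``flow_<label>.csv`` traces (columns ``time_s,value``) and a ``manifest.json``
with morphometrics, tunnel geometry, the speed schedule, phase metadata and,
for synthetic trials, the ground-truth block.  Writing is deterministic:
identical trials produce byte-identical files.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .types import (
    FishMorphometrics,
    FlowTrace,
    Phase,
    PhaseData,
    PO2Trace,
    SpeedStep,
    SyntheticTruth,
    TrialRecord,
    TunnelGeometry,
)

_FLOAT_FMT = "%.10g"


def _phase_label(phase: Phase) -> str:
    if phase.kind == "rest":
        return "rest"
    if phase.kind == "recovery":
        return f"rec_{int(phase.minute):03d}min"
    if phase.exhaustion:
        return "exhaustion"
    return f"swim_{phase.speed_bl_s:.2f}"


def _write_trace_csv(path: Path, time_s: np.ndarray, values: np.ndarray) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("time_s,value\n")
        for t, v in zip(time_s, values):
            fh.write(f"{_FLOAT_FMT % t},{_FLOAT_FMT % v}\n")


def _read_trace_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return data[:, 0], data[:, 1]


def write_trial(trial: TrialRecord, out_dir: str | Path) -> Path:
    """Write one trial to ``out_dir/trial_<fish_id>/``; returns the directory."""
    tdir = Path(out_dir) / f"trial_{trial.fish_id}"
    tdir.mkdir(parents=True, exist_ok=True)
    phase_entries = []
    for pd_ in trial.phases:
        label = _phase_label(pd_.phase)
        entry: dict = {
            "kind": pd_.phase.kind,
            "speed_bl_s": pd_.phase.speed_bl_s,
            "minute": pd_.phase.minute,
            "exhaustion": pd_.phase.exhaustion,
            "po2_file": None,
            "flow_file": None,
        }
        if pd_.po2 is not None:
            fname = f"po2_{label}.csv"
            _write_trace_csv(tdir / fname, pd_.po2.time_s, pd_.po2.po2_pct_sat)
            entry["po2_file"] = fname
            entry["po2_truncated"] = pd_.po2.truncated
        if pd_.flow is not None:
            fname = f"flow_{label}.csv"
            _write_trace_csv(tdir / fname, pd_.flow.time_s, pd_.flow.flow_ml_min)
            entry["flow_file"] = fname
            entry["flow_sample_rate_hz"] = pd_.flow.sample_rate_hz
        phase_entries.append(entry)
    manifest = {
        "fish_id": trial.fish_id,
        "fish": dataclasses.asdict(trial.fish),
        "tunnel": dataclasses.asdict(trial.tunnel),
        "temp_c": trial.temp_c,
        "salinity_ppt": trial.salinity_ppt,
        "ramp_c_per_h": trial.ramp_c_per_h,
        "steps": [dataclasses.asdict(s) for s in trial.steps],
        "phases": phase_entries,
        "truth": dataclasses.asdict(trial.truth) if trial.truth else None,
    }
    with open(tdir / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tdir


def read_trial(trial_dir: str | Path) -> TrialRecord:
    """Reconstruct a TrialRecord from a trial directory."""
    tdir = Path(trial_dir)
    with open(tdir / "manifest.json") as fh:
        m = json.load(fh)
    fish = FishMorphometrics(**m["fish"])
    tunnel = TunnelGeometry(**m["tunnel"])
    phases = []
    for e in m["phases"]:
        phase = Phase(e["kind"], e["speed_bl_s"], e["minute"], e["exhaustion"])
        po2 = flow = None
        if e["po2_file"]:
            t, v = _read_trace_csv(tdir / e["po2_file"])
            po2 = PO2Trace(t, v, m["temp_c"], m["salinity_ppt"], phase,
                           truncated=e.get("po2_truncated", False))
        if e["flow_file"]:
            t, v = _read_trace_csv(tdir / e["flow_file"])
            flow = FlowTrace(t, v, e["flow_sample_rate_hz"], phase)
        phases.append(PhaseData(phase, po2, flow))
    truth = SyntheticTruth(**m["truth"]) if m.get("truth") else None
    return TrialRecord(
        fish_id=m["fish_id"],
        fish=fish,
        tunnel=tunnel,
        temp_c=m["temp_c"],
        salinity_ppt=m["salinity_ppt"],
        steps=[SpeedStep(**s) for s in m["steps"]],
        phases=phases,
        ramp_c_per_h=m.get("ramp_c_per_h", 1.0),
        truth=truth,
    )


def list_trial_dirs(root: str | Path) -> list[Path]:
    return sorted(p for p in Path(root).iterdir()
                  if p.is_dir() and p.name.startswith("trial_"))
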