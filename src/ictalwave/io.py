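"""Configuration parsing, result serialization and run manifests.

Configurations are YAML mappings mirroring ScenarioConfig (nested
sections ``spatial``, ``ions``, ``synapses``, ``pop_E``, ``pop_I``);
unknown keys are rejected. A run directory contains the site traces as
delimited text with unit-annotated headers, the space-time fields in a
named-array binary container (.npz), and a manifest with the resolved
configuration, seed, package version and per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import FIELD_NAMES, Recording
from .params import (IonParams, ScenarioConfig, SpatialParams,
                     SynapsesParams, default_E_population,
                     default_I_population)

TRACE_FILE = "traces.csv"
FIELDS_FILE = "fields.npz"
MANIFEST_FILE = "manifest.yaml"

_UNITS = {
    "K_o": "mM", "U_E": "mV", "U_I": "mV", "nu_E": "1/ms", "nu_I": "1/ms",
    "V_repE": "mV", "V_repI": "mV", "I_hold": "uA/cm^2", "V_GABA_E": "mV",
    "V_GABA_I": "mV", "Na_i_E": "mM", "Cl_i_E": "mM", "Cl_i_I": "mM",
    "v": "ratio", "Ca_i": "mM", "mass_E": "1", "mass_I": "1",
    "x_glu": "1", "x_gaba": "1",
}


def _set_fields(obj, data: dict, path: str):
    for key, val in data.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown configuration key {path}{key!r}")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _set_fields(cur, val, f"{path}{key}.")
        else:
            setattr(obj, key, type(cur)(val) if cur is not None else val)
    return obj


def config_from_dict(data: dict) -> ScenarioConfig:
    """Build a ScenarioConfig from a nested mapping; unknown keys raise."""
    cfg = ScenarioConfig()
    cfg.spatial = SpatialParams()
    cfg.ions = IonParams()
    cfg.synapses = SynapsesParams()
    cfg.pop_E = default_E_population()
    cfg.pop_I = default_I_population()
    _set_fields(cfg, data or {}, "")
    cfg.__post_init__()
    cfg.spatial.__post_init__()
    return cfg


def load_config(path) -> ScenarioConfig:
    """Read a YAML scenario configuration; empty file = full defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def config_to_dict(cfg: ScenarioConfig) -> dict:
    d = dataclasses.asdict(cfg)
    # tuples are not YAML-native
    d["spatial"]["electrode_fracs"] = list(cfg.spatial.electrode_fracs)
    return d


def save_config(cfg: ScenarioConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_recording(rec: Recording, out_dir, extra_meta=None):
    """Write a Recording to ``out_dir``; returns the manifest dict.

    Traces go to a CSV with unit-annotated column names, fields to a
    compressed .npz with named arrays, and the manifest (resolved
    config, seed, version, wall time, checksums) to YAML.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = {"time_s": rec.t_trace}
    for i, name in enumerate(rec.columns):
        base = name.rsplit("_S", 1)[0] if "_S" in name else name
        unit = _UNITS.get(base, "")
        cols[f"{name}[{unit}]" if unit else name] = rec.trace[:, i]
    pd.DataFrame(cols).to_csv(out / TRACE_FILE, index=False,
                              float_format="%.8g")
    arrays = {"time_s": rec.t_fields, "x_mm": rec.x}
    for i, name in enumerate(rec.field_names):
        arrays[name] = rec.fields[:, i, :]
    np.savez_compressed(out / FIELDS_FILE, **arrays)
    manifest = {
        "package": "ictalwave",
        "version": __version__,
        "written_utc": _time.strftime("%Y-%m-%dT%H:%M:%SZ", _time.gmtime()),
        "seed": rec.config.seed,
        "scenario": rec.config.scenario,
        "electrode_idx": list(rec.electrode_idx),
        "electrode_x_mm": list(rec.electrode_x),
        "config": config_to_dict(rec.config),
        "files": {},
    }
    if extra_meta:
        manifest.update(extra_meta)
    for f in (TRACE_FILE, FIELDS_FILE):
        manifest["files"][f] = _sha256(out / f)
    with open(out / MANIFEST_FILE, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_recording(run_dir) -> Recording:
    """Load a run directory back into a Recording (checksums verified)."""
    run = Path(run_dir)
    with open(run / MANIFEST_FILE) as fh:
        manifest = yaml.safe_load(fh)
    for f, digest in manifest["files"].items():
        actual = _sha256(run / f)
        if actual != digest:
            raise IOError(f"checksum mismatch for {run / f}")
    df = pd.read_csv(run / TRACE_FILE)
    t_trace = df["time_s"].to_numpy()
    names = [c.split("[")[0] for c in df.columns if c != "time_s"]
    trace = df[[c for c in df.columns if c != "time_s"]].to_numpy()
    npz = np.load(run / FIELDS_FILE)
    t_fields = npz["time_s"]
    x = npz["x_mm"]
    fields = np.stack([npz[n] for n in FIELD_NAMES], axis=1)
    cfg = config_from_dict(manifest["config"])
    return Recording(
        t_trace=t_trace, trace=trace, columns=tuple(names),
        t_fields=t_fields, fields=fields, field_names=FIELD_NAMES,
        x=x, electrode_idx=tuple(manifest["electrode_idx"]),
        electrode_x=tuple(manifest["electrode_x_mm"]), config=cfg)


def analysis_report(rec: Recording, out_path=None, baseline=None):
    """Per-discharge events and summary statistics as a JSON-able dict."""
    from . import analysis as an
    baseline = rec.config.ions.K_bath if baseline is None else baseline
    t = rec.t_trace
    report = {"scenario": rec.config.scenario, "seed": rec.config.seed,
              "sites": {}, "front_speeds_mm_s": None}
    event_sets = []
    for site in ("S1", "S2"):
        K = rec.col(f"K_o_{site}")
        events = an.detect_id_events(t, K, baseline=baseline)
        event_sets.append(events)
        report["sites"][site] = [
            {"onset_s": e.onset, "offset_s": e.offset, "peak_K_mM": e.peak_K,
             "duration_s": e.duration} for e in events]
    stats = an.id_statistics(event_sets)
    report["statistics"] = {
        k: {"n": s.n, "median": s.median, "iqr": list(s.iqr)}
        for k, s in stats.items()}
    ko_idx = list(rec.field_names).index("K_o")
    speeds = an.slowest_front_speeds(rec.t_fields, rec.x,
                                     rec.fields[:, ko_idx, :])
    report["front_speeds_mm_s"] = speeds
    delays = an.speed_from_delay(t, rec.col("K_o_S1"), rec.col("K_o_S2"),
                                 rec.electrode_distance, baseline=baseline)
    report["delay_speeds_mm_s"] = [
        {"speed": d.speed, "lag_s": d.lag, "status": d.reason} for d in delays]
    if out_path is not None:
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report
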