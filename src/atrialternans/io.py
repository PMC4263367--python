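"""Configuration, trace serialization, run manifests and reference fixtures.

Traces are written either as delimited text (header row carries variable
names with units; portable, 1e-9-relative round-trip) or as a binary NPZ
container (exact round-trip).  Every protocol run directory carries one YAML
manifest sufficient to re-run the job.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants as c
from .engine import TraceSet
from .parameters import ModelParameters, make_parameters

#: units for trace headers, keyed by variable name prefix
UNITS = {"vm": "mV", "ca_i": "mM", "ca_j": "mM", "ca_sl": "mM",
         "ca_sr": "mM", "ca_jsr": "mM", "ca_nsr": "mM",
         "na_j": "mM", "na_sl": "mM", "na_i": "mM", "k_i": "mM",
         "time": "ms"}
_CURRENT_UNITS = {n: ("mM/ms" if n.startswith("j_") else "A/F")
                  for n in c.CURRENT_NAMES}
UNITS.update(_CURRENT_UNITS)


def _unit(name: str) -> str:
    return UNITS.get(name, "1")


# ---------------------------------------------------------------------------
# configuration documents
# ---------------------------------------------------------------------------
_CONFIG_KEYS = {"variant", "chamber", "ryr_formulation", "scales",
                "fast_buffers", "stim_amplitude", "stim_duration",
                "protocol", "cl", "n_beats", "dt", "out", "seed"}


def load_config(path) -> dict:
    """Load and validate a protocol configuration document.

    Unknown keys are rejected with a case-insensitive suggestion; parameter
    names inside ``scales`` are validated against the model's table names.
    Defaults are filled in and echoed back.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    for key in raw:
        if key not in _CONFIG_KEYS:
            low = {k.lower(): k for k in _CONFIG_KEYS}
            hint = f"; did you mean {low[key.lower()]!r}?" \
                if key.lower() in low else ""
            raise KeyError(f"unknown configuration key {key!r}{hint}")
    params = ModelParameters.from_dict(raw)   # validates scales & enums
    cfg = {
        "variant": params.variant,
        "chamber": params.chamber,
        "ryr_formulation": params.ryr_formulation,
        "scales": dict(params.scales),
        "fast_buffers": params.fast_buffers,
        "stim_amplitude": params.stim_amplitude,
        "stim_duration": params.stim_duration,
        "protocol": raw.get("protocol", "steady"),
        "cl": float(raw.get("cl", 400.0)),
        "n_beats": int(raw.get("n_beats", 10)),
        "dt": float(raw.get("dt", 0.02)),
        "seed": int(raw.get("seed", 0)),
        "out": raw.get("out"),
    }
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: v for k, v in cfg.items() if v is not None}, fh,
                       sort_keys=True)


def params_from_config(cfg: dict) -> ModelParameters:
    return make_parameters(cfg["variant"], cfg["chamber"], cfg["scales"],
                           ryr_formulation=cfg["ryr_formulation"],
                           fast_buffers=cfg["fast_buffers"],
                           stim_amplitude=cfg["stim_amplitude"],
                           stim_duration=cfg["stim_duration"])


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------
def write_traces(ts: TraceSet, path, backend: str = "text") -> None:
    """Write a TraceSet; ``backend`` is ``text`` (TSV) or ``binary`` (NPZ)."""
    path = Path(path)
    meta = {"dt": ts.dt, "cl": ts.cl, "beat_samples": ts.beat_samples,
            "meta": ts.meta}
    if backend == "binary":
        np.savez_compressed(
            path, __meta__=np.frombuffer(
                json.dumps(meta, default=str).encode(), dtype=np.uint8),
            **ts.data)
        return
    if backend != "text":
        raise ValueError("backend must be 'text' or 'binary'")
    cols = {"time [ms]": ts.time}
    cols.update({f"{k} [{_unit(k)}]": v for k, v in ts.data.items()})
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# dt_ms={ts.dt!r} cl_ms={ts.cl!r} "
                 f"beat_samples={ts.beat_samples}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_traces(path) -> TraceSet:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            data = {k: z[k] for k in z.files if k != "__meta__"}
        return TraceSet(dt=meta["dt"], data=data,
                        beat_samples=meta["beat_samples"], cl=meta["cl"],
                        meta=meta.get("meta", {}))
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing metadata header line")
        kv = dict(item.split("=") for item in header[1:].split())
        df = pd.read_csv(fh, sep="\t")
    data = {}
    for col in df.columns:
        if col.startswith("time"):
            continue
        if "[" not in col:
            raise ValueError(f"column {col!r} lacks a units annotation")
        name = col.split(" [")[0]
        data[name] = df[col].to_numpy()
    return TraceSet(dt=float(kv["dt_ms"]), data=data,
                    beat_samples=int(kv["beat_samples"]),
                    cl=float(kv["cl_ms"]))


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------
def write_manifest(outdir, cfg: dict, params: ModelParameters,
                   stages: dict | None = None, seed: int | None = None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__
    manifest = {
        "config": {k: v for k, v in cfg.items() if v is not None},
        "code_version": __version__,
        "parameter_hash": params.digest(),
        "seed": seed,
        "wall_time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": stages or {},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True, default_flow_style=False)
    return manifest


# ---------------------------------------------------------------------------
# reference fixtures
# ---------------------------------------------------------------------------
def make_fixtures(seed: int = 0, outdir=None, dt: float = 0.02) -> dict:
    """Generate the small canonical reference bundle used as regression
    fixtures: 5 beats control @750-ms CL, 5 beats cAF (ki_Ca x0.5) @400-ms
    CL, one AP-clamp cycle, and one 10-node cable beat.  Deterministic for a
    given seed/config; returns the bundle with metric summaries and trace
    hashes."""
    from . import metrics as mx
    from .engine import (ClampSpec, PacingSchedule, build_ap_waveform,
                         integrate)
    from .model import initial_state

    rng = np.random.default_rng(seed)  # reserved for future noisy fixtures
    out = {"seed": seed}

    def _digest(ts):
        h = hashlib.sha256()
        for k in sorted(ts.data):
            h.update(np.round(ts.data[k], 9).tobytes())
        return h.hexdigest()[:16]

    ctrl = make_parameters("control", "LA", stim_amplitude=12.5)
    y = initial_state(ctrl)
    # 30 conditioning beats: the control rhythm settles slowly at 750-ms CL
    y = integrate(y, ctrl, PacingSchedule([(750.0, 30)], 12.5, 2.0),
                  dt, ("vm",)).final_state
    ts = integrate(y, ctrl, PacingSchedule([(750.0, 5)], 12.5, 2.0),
                   dt, ("vm", "ca_i"))
    out["control_750"] = {
        "apd": mx.apd_series(ts).tolist(),
        "cat": mx.cat_series(ts).tolist(),
        "hash": _digest(ts),
    }
    if outdir:
        write_traces(ts, Path(outdir) / "control_750.tsv")

    alt = make_parameters("cAF", "LA", {"ki_Ca": 0.5}, stim_amplitude=12.5)
    y = initial_state(alt)
    y = integrate(y, alt, PacingSchedule([(750.0, 10), (400.0, 30)],
                                         12.5, 2.0), dt, ("vm",)).final_state
    ts = integrate(y, alt, PacingSchedule([(400.0, 5)], 12.5, 2.0),
                   dt, ("vm", "ca_i"))
    out["caf_alt_400"] = {
        "apd": mx.apd_series(ts).tolist(),
        "cat": mx.cat_series(ts).tolist(),
        "hash": _digest(ts),
    }
    if outdir:
        write_traces(ts, Path(outdir) / "caf_alt_400.tsv")

    wave = build_ap_waveform(cl=400.0, dt=dt)
    y = initial_state(alt)
    ts = integrate(y, alt, PacingSchedule([(400.0, 1)], 0.0, 2.0), dt,
                   ("vm", "ca_i"), clamp=ClampSpec("vm", wave))
    out["ap_clamp_cycle"] = {"hash": _digest(ts),
                             "vm_max": float(ts.data["vm"].max()),
                             "vm_rest": float(ts.data["vm"].min())}

    from .cable import CableConfig, run_cable_protocol
    cfg = CableConfig(length=1.0, dx=0.1, sigma=0.2, record_pos=0.9)
    y0 = initial_state(ctrl)
    y0 = integrate(y0, ctrl, PacingSchedule([(750.0, 10)], 12.5, 2.0),
                   dt, ("vm",)).final_state
    _, tsc, _ = run_cable_protocol(
        cfg, ctrl, PacingSchedule([(500.0, 1)], 25.0, 2.0), init_state=y0)
    out["cable_beat"] = {"hash": _digest(tsc),
                         "captured": bool(tsc.captured.all())}
    if outdir:
        with open(Path(outdir) / "fixtures.json", "w") as fh:
            json.dump(out, fh, indent=1)
    return out
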