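"""Configuration files, provenance manifests, seed fan-out and the
end-to-end reproduction driver."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assembly import build_stable_ensemble
from .dynamics import SimulationConfig
from .fluctuation_experiments import (
    amplitude_sweep,
    compare_groups,
    cooperative_competitive_ensembles,
    frequency_sweep,
)
from .synthetic_data import ModulationSpec, PanelSpec, generate_base_panel, save_panel

__all__ = [
    "RunManifest",
    "load_config",
    "save_config",
    "child_seed",
    "run_reproduction",
]

# config-file keys (parameter-table style) -> SimulationConfig fields
_KEY_MAP = {
    "N_c": "n_c",
    "N_s": "n_s",
    "N_gen": "n_gen",
    "delta": "delta",
    "N_ext": "n_ext",
    "f_p": "f_p",
    "S_0": "s0",
    "f_pH": "f_ph",
    "dpH": "dph",
    "p0": "p0",
    "rel_tol": "rel_tol",
    "abs_tol": "abs_tol",
    "seed": "seed",
}


def load_config(path) -> SimulationConfig:
    """Read a YAML config; unknown keys or out-of-range values error.

    An empty file yields all defaults (N_c=20, N_s=10000, N_gen=100,
    pH_rng=[5.1, 7.5], delta=0.1, N_ext=1e-6, f_p=0.2, S_0=1e-4,
    f_pH=1, dpH=0.5).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    kwargs = {}
    unknown = []
    for key, val in raw.items():
        if key == "pH_rng":
            lo, hi = val
            kwargs["ph_min"] = float(lo)
            kwargs["ph_max"] = float(hi)
        elif key in _KEY_MAP:
            kwargs[_KEY_MAP[key]] = val
        else:
            unknown.append(key)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    try:
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def save_config(path, config: SimulationConfig) -> None:
    d = asdict(config)
    out = {k: d[v] for k, v in _KEY_MAP.items()}
    out["pH_rng"] = [d["ph_min"], d["ph_max"]]
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def child_seed(master_seed: int, label: str) -> int:
    """Stable per-stage seed: adding a stage never perturbs others."""
    h = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(h[:8], "big") % (2**63 - 1)


@dataclass
class RunManifest:
    """Everything needed to re-run an experiment bit-identically."""

    config: dict
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    panel_source: str = "generator"
    panel_spec: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    version: str = __version__

    def config_hash(self) -> str:
        blob = json.dumps({"config": self.config, "seed": self.seed,
                           "panel": self.panel_spec}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        d = asdict(self)
        d["config_hash"] = self.config_hash()
        Path(path).write_text(json.dumps(d, indent=2, default=str))


def run_reproduction(
    scale: float,
    outdir,
    seed: int = 0,
    config: SimulationConfig | None = None,
    amplitudes=(0.0, 0.25, 0.5, 1.0),
    frequencies=(1e-3, 1e-2, 0.05, 0.2, 1.0, 10.0),
) -> RunManifest:
    """End-to-end pipeline at a fraction of the full ensemble size.

    Generates a synthetic panel, assembles robust stable communities,
    runs the amplitude and frequency sweeps and the cooperative vs
    competitive comparison, and writes CSV/JSON outputs plus a manifest.
    """
    if scale <= 0:
        raise ValueError("scale must be positive (empty ensemble)")
    if config is None:
        config = SimulationConfig(seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_comm = max(1, int(round(scale * config.n_s)))
    manifest = RunManifest(config=asdict(config), seed=seed)
    t0 = time.time()

    panel_spec = PanelSpec(seed=child_seed(seed, "panel"))
    responses, C = generate_base_panel(panel_spec)
    save_panel(outdir / "panel", responses, C, panel_spec)
    manifest.panel_spec = asdict(panel_spec)
    manifest.timings_s["panel"] = time.time() - t0

    mod = ModulationSpec(f_p=config.f_p)
    t0 = time.time()
    ensemble, counts = build_stable_ensemble(
        (responses, C), n_comm, config, mod,
        master_seed=child_seed(seed, "assembly"),
    )
    manifest.outputs["assembly_counts"] = counts
    manifest.timings_s["assembly"] = time.time() - t0

    t0 = time.time()
    amp = amplitude_sweep(ensemble, amplitudes, f=0.2, config=config)
    amp.values.to_csv(outdir / "amplitude_sweep.csv", index=False)
    amp.summary.to_csv(outdir / "amplitude_summary.csv", index=False)
    manifest.timings_s["amplitude_sweep"] = time.time() - t0

    t0 = time.time()
    freq = frequency_sweep(ensemble, frequencies, dph=0.5, config=config)
    freq.values.to_csv(outdir / "frequency_sweep.csv", index=False)
    freq.summary.to_csv(outdir / "frequency_summary.csv", index=False)
    manifest.timings_s["frequency_sweep"] = time.time() - t0

    t0 = time.time()
    groups = cooperative_competitive_ensembles(
        responses, C, max(5, n_comm // 2), config, mod,
        master_seed=child_seed(seed, "groups"),
    )
    from .dynamics import PHDriver
    from .fluctuation_experiments import fluctuation_response

    drv = PHDriver.sinusoid(config.p0, 0.5, 0.2, clamp_lo=config.ph_min,
                            clamp_hi=config.ph_max)
    diss = {
        name: [fluctuation_response(sc, drv, config) for sc in ens]
        for name, ens in groups.items()
    }
    cmp_res = compare_groups(diss["competitive"], diss["cooperative"])
    manifest.outputs["group_comparison"] = asdict(cmp_res)
    manifest.timings_s["groups"] = time.time() - t0

    manifest.stage_seeds = {
        s: child_seed(seed, s) for s in ("panel", "assembly", "groups")
    }
    summary = {
        "n_communities": n_comm,
        "amplitude_summary": amp.summary.to_dict(orient="records"),
        "frequency_summary": freq.summary.to_dict(orient="records"),
        "group_comparison": asdict(cmp_res),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    manifest.outputs["summary"] = str(outdir / "summary.json")
    manifest.save(outdir / "manifest.json")
    return manifest
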