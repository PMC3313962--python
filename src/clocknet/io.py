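"""Configuration files, result serialization, fixtures, and run manifests.

Configs are TOML with sections [params], [network], [modulation] and
[protocol]; keys missing from a user file fall back to the packaged
``defaults.toml``, unknown keys are rejected by name.  Trajectories are
written as long-format CSV (time, light, neuron, M, P0, P1, P2, PN) with a
JSON sidecar echoing the resolved configuration, and every output directory
receives a manifest with SHA-256 checksums sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ClockParams, LightSchedule, PARAM_ORDER
from .network import (ModulationSpec, NetworkConfig, SimulationResult,
                      MODULATION_TARGETS, SPECIES)
from .rhythm import RhythmSummary

__all__ = [
    "load_config",
    "save_config",
    "config_to_dict",
    "make_fixture",
    "write_outputs",
    "read_trajectories",
    "RunManifest",
]

log = logging.getLogger("clocknet")

_NETWORK_KEYS = ("N", "sigma", "dt", "seed", "ic_sd", "record_every", "burn_days")
_MODULATION_KEYS = ("targets", "gain_k1", "gain_k2", "gain_vd")
_PROTOCOL_KEYS = ("ld_days", "dd_days", "photoperiod_on", "day_length")


class ConfigError(ValueError):
    """Configuration file violates the schema."""


def _defaults() -> dict:
    text = resources.files("clocknet").joinpath("defaults.toml").read_text()
    return tomllib.loads(text)


def _merge_section(data: dict, section: str, allowed: tuple) -> dict:
    base = dict(_defaults()[section])
    extra = data.get(section, {})
    if not isinstance(extra, dict):
        raise ConfigError(f"section [{section}] must be a table")
    for key in extra:
        if key not in allowed:
            raise ConfigError(f"unknown key '{key}' in section [{section}]")
    base.update(extra)
    return base


def config_from_dict(data: dict) -> NetworkConfig:
    """Build a validated :class:`NetworkConfig` from nested plain data."""
    for section in data:
        if section not in ("params", "network", "modulation", "protocol"):
            raise ConfigError(f"unknown section [{section}]")
    try:
        params = ClockParams(**_merge_section(data, "params", PARAM_ORDER))
        net = _merge_section(data, "network", _NETWORK_KEYS)
        mod = _merge_section(data, "modulation", _MODULATION_KEYS)
        proto = _merge_section(data, "protocol", _PROTOCOL_KEYS)
        modulation = ModulationSpec(targets=frozenset(mod["targets"]),
                                    gain_k1=mod["gain_k1"], gain_k2=mod["gain_k2"],
                                    gain_vd=mod["gain_vd"])
        schedule = LightSchedule(**proto)
        return NetworkConfig(params=params, modulation=modulation,
                             schedule=schedule, **net)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path | None = None) -> NetworkConfig:
    """Read a TOML config; missing keys (or ``path=None``) use the defaults."""
    if path is None:
        return config_from_dict({})
    text = Path(path).read_text()
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return config_from_dict(data)


def config_to_dict(config: NetworkConfig) -> dict:
    """Nested plain-data view of a config (the serialized form)."""
    m = config.modulation
    s = config.schedule
    return {
        "params": config.params.as_dict(),
        "network": {"N": config.N, "sigma": config.sigma, "dt": config.dt,
                    "seed": config.seed, "ic_sd": config.ic_sd,
                    "record_every": config.record_every,
                    "burn_days": config.burn_days},
        "modulation": {"targets": sorted(m.targets), "gain_k1": m.gain_k1,
                       "gain_k2": m.gain_k2, "gain_vd": m.gain_vd},
        "protocol": {"ld_days": s.ld_days, "dd_days": s.dd_days,
                     "photoperiod_on": s.photoperiod_on,
                     "day_length": s.day_length},
    }


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {v!r}")


def save_config(config: NetworkConfig, path: str | Path) -> Path:
    """Write a config as TOML; ``load_config`` of the file round-trips."""
    lines = []
    for section, table in config_to_dict(config).items():
        lines.append(f"[{section}]")
        lines.extend(f"{k} = {_toml_value(v)}" for k, v in table.items())
        lines.append("")
    path = Path(path)
    path.write_text("\n".join(lines))
    return path


# ---------------------------------------------------------------------------
# synthetic fixtures with known ground truth
# ---------------------------------------------------------------------------

def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Synthetic trace bundles for exercising the rhythm analysis.

    Returns ``(times, traces, truth)`` with ``traces`` of shape (N, T) and
    ``truth`` a dict of the generating parameters.

    kinds
    -----
    ``cosine_bundle``
        N cosines sharing (M0, A, tau) with per-neuron phases ``phis``
        (scalar broadcasts; default all zero).
    ``drifting_bundle``
        per-neuron periods drawn Normal(tau, tau_sd) with random phases.
    ``noise_bundle``
        N independent Gaussian white-noise traces around M0 with SD ``sd``.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    N = int(p.pop("N", 10))
    days = float(p.pop("days", 6.0))
    dt = float(p.pop("dt", 0.1))
    times = np.arange(0.0, days * 24.0 + dt / 2, dt)
    M0 = float(p.pop("M0", 2.0))

    if kind == "cosine_bundle":
        A = float(p.pop("A", 1.0))
        tau = float(p.pop("tau", 24.0))
        phis = np.broadcast_to(np.asarray(p.pop("phis", 0.0), dtype=float), (N,))
        traces = M0 + A * np.cos(2 * np.pi * (times[None, :] - phis[:, None]) / tau)
        truth = {"M0": M0, "A": A, "tau": tau, "phis": phis.copy()}
    elif kind == "drifting_bundle":
        tau = float(p.pop("tau", 24.0))
        tau_sd = float(p.pop("tau_sd", 1.0))
        A = float(p.pop("A", 1.0))
        taus = rng.normal(tau, tau_sd, N)
        phis = rng.uniform(0.0, tau, N)
        traces = M0 + A * np.cos(2 * np.pi * (times[None, :] - phis[:, None]) / taus[:, None])
        truth = {"M0": M0, "A": A, "taus": taus, "phis": phis}
    elif kind == "noise_bundle":
        sd = float(p.pop("sd", 1.0))
        traces = M0 + rng.normal(0.0, sd, (N, times.size))
        truth = {"M0": M0, "sd": sd}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if p:
        raise ValueError(f"unknown fixture parameters: {sorted(p)}")
    return times, traces, truth


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Inventory of one output directory, sufficient to reproduce the run."""

    config: dict
    version: str
    seed: int
    created: str
    files: dict  # name -> sha256

    def content_equal(self, other: "RunManifest") -> bool:
        """Equality ignoring the creation timestamp."""
        return (self.config == other.config and self.version == other.version
                and self.seed == other.seed and self.files == other.files)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def result_to_dataframe(result: SimulationResult) -> pd.DataFrame:
    """Long-format trajectory table (one row per time point and neuron)."""
    N, _, T = result.states.shape
    frames = []
    for i in range(N):
        df = pd.DataFrame({"time": result.times, "light": result.light,
                           "neuron": i})
        for c, name in enumerate(SPECIES):
            df[name] = result.states[i, c, :]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def read_trajectories(path: str | Path):
    """Read a trajectories.csv back into (times, light, states (N,5,T))."""
    df = pd.read_csv(path)
    neurons = np.sort(df["neuron"].unique())
    t0 = df[df["neuron"] == neurons[0]]
    times = t0["time"].to_numpy()
    light = t0["light"].to_numpy()
    states = np.empty((neurons.size, len(SPECIES), times.size))
    for idx, i in enumerate(neurons):
        sub = df[df["neuron"] == i]
        for c, name in enumerate(SPECIES):
            states[idx, c, :] = sub[name].to_numpy()
    return times, light, states


def _summary_to_dict(summary: RhythmSummary) -> dict:
    return {
        "procedure": summary.procedure,
        "window": list(summary.window),
        "mean_tau": summary.mean_tau, "sd_tau": summary.sd_tau,
        "mean_phi": summary.mean_phi, "mean_phi_arith": summary.mean_phi_arith,
        "sd_phi": summary.sd_phi, "R": summary.R,
        "per_neuron": [dataclasses.asdict(f) for f in summary.per_neuron],
        "ensemble_fit": dataclasses.asdict(summary.ensemble_fit)
        if summary.ensemble_fit is not None else None,
    }


def write_outputs(obj, out_dir: str | Path, seed: int | None = None) -> RunManifest:
    """Write a result/summary/scan table to ``out_dir`` with a manifest.

    Accepts a :class:`SimulationResult`, a :class:`RhythmSummary`, or a tidy
    scan ``DataFrame``.  Existing files are overwritten with a warning.  The
    manifest (manifest.json) lists SHA-256 checksums of every written file;
    two runs with equal seeds and configs produce manifests equal up to the
    timestamp.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    written: list[Path] = []
    config_dict: dict = {}
    if isinstance(obj, SimulationResult):
        config_dict = config_to_dict(obj.config)
        seed = obj.config.seed if seed is None else seed
        traj = out / "trajectories.csv"
        if traj.exists():
            log.warning("overwriting %s", traj)
        result_to_dataframe(obj).to_csv(traj, index=False, float_format="%.6g")
        sidecar = out / "config.json"
        sidecar.write_text(json.dumps(
            {"config": config_dict, "n_clipped": obj.n_clipped}, indent=2))
        written += [traj, sidecar]
    elif isinstance(obj, RhythmSummary):
        f = out / "summary.json"
        if f.exists():
            log.warning("overwriting %s", f)
        f.write_text(json.dumps(_summary_to_dict(obj), indent=2))
        written.append(f)
    elif isinstance(obj, pd.DataFrame):
        f = out / "scan.csv"
        if f.exists():
            log.warning("overwriting %s", f)
        obj.to_csv(f, index=False, float_format="%.6g")
        written.append(f)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")

    manifest = RunManifest(
        config=config_dict, version=__version__,
        seed=-1 if seed is None else int(seed),
        created=datetime.now(timezone.utc).isoformat(),
        files={p.name: _sha256(p) for p in written})
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2))
    return manifest


def read_manifest(path: str | Path) -> RunManifest:
    data = json.loads(Path(path).read_text())
    return RunManifest(**data)
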