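"""Config parsing and trajectory serialization.

Model configs are structured files (YAML, JSON, or TOML, chosen by
extension) with keys ``genotypes, phenotypes, fitness, mu, phi, R, m, S,
sigma, N``; unknown keys are errors.  Trajectories are written as TSV
(17 significant digits, so read-write round-trips are exact to double
precision) with a JSON sidecar carrying the model hash, seed, dt and N.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import PrGPModel
from .trajectory import Trajectory

__all__ = ["load_model_config", "save_model_config", "RunConfig",
           "load_config", "write_trajectories", "read_trajectories"]

_TSV_COLUMNS = ["trial", "dilution", "time", "genotype", "phenotype",
                "count", "frequency", "mean_fitness"]


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    try:
        if suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        elif suffix == ".json":
            data = json.loads(text)
        elif suffix == ".toml":
            import tomllib
            data = tomllib.loads(text)
        else:
            raise ValueError(f"unsupported config extension {suffix!r} "
                             "(use .yaml, .json or .toml)")
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"{path} must contain a mapping at top level")
    return data


def load_model_config(path: str | Path) -> PrGPModel:
    return PrGPModel.from_dict(_load_structured(path))


def save_model_config(model: PrGPModel, path: str | Path) -> None:
    path = Path(path)
    d = model.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    elif path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=1))
    else:
        raise ValueError(f"unsupported output extension {path.suffix!r} "
                         "(use .yaml or .json)")


@dataclass
class RunConfig:
    """Validated run specification for the CLI engines."""

    model: PrGPModel
    engine: str = "prosed"            # "prosed" | "ode"
    dt: float | None = None
    n_dilutions: int = 100
    t_max: float | None = None
    trials: int = 1
    seed: int = 0
    out: str | None = None
    init: np.ndarray | None = None    # frequency tensor; uniform if absent

    _KEYS = {"model", "engine", "dt", "n_dilutions", "t_max", "trials",
             "seed", "out", "init"}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run config; errors carry the offending key."""
    data = _load_structured(path)
    unknown = set(data) - RunConfig._KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "model" not in data:
        raise ValueError("missing config key: model")
    model_spec = data["model"]
    if isinstance(model_spec, str):
        model_path = Path(model_spec)
        if not model_path.is_absolute():
            model_path = Path(path).parent / model_path
        if not model_path.exists():
            raise ValueError(f"model: referenced file {model_path} "
                             "does not exist")
        model = load_model_config(model_path)
    elif isinstance(model_spec, dict):
        model = PrGPModel.from_dict(model_spec)
    else:
        raise ValueError("model: must be an inline mapping or a file path")

    engine = data.get("engine", "prosed")
    if engine not in ("prosed", "ode"):
        raise ValueError(f"engine: {engine!r} is not one of prosed, ode")
    n_dilutions = int(data.get("n_dilutions", 100))
    if n_dilutions < 1:
        raise ValueError("n_dilutions: must be >= 1")
    trials = int(data.get("trials", 1))
    if trials < 1:
        raise ValueError("trials: must be >= 1")
    dt = data.get("dt")
    if dt is not None and float(dt) <= 0:
        raise ValueError("dt: must be positive")
    t_max = data.get("t_max")
    if t_max is not None and float(t_max) <= 0:
        raise ValueError("t_max: must be positive")
    init = data.get("init")
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape != model.shape:
            raise ValueError(f"init: shape {init.shape} != model shape "
                             f"{model.shape}")
    return RunConfig(model=model, engine=engine,
                     dt=None if dt is None else float(dt),
                     n_dilutions=n_dilutions,
                     t_max=None if t_max is None else float(t_max),
                     trials=trials, seed=int(data.get("seed", 0)),
                     out=data.get("out"), init=init)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = {"model": cfg.model.to_dict(), "engine": cfg.engine,
         "n_dilutions": cfg.n_dilutions, "trials": cfg.trials,
         "seed": cfg.seed}
    if cfg.dt is not None:
        d["dt"] = cfg.dt
    if cfg.t_max is not None:
        d["t_max"] = cfg.t_max
    if cfg.out is not None:
        d["out"] = cfg.out
    if cfg.init is not None:
        d["init"] = cfg.init.tolist()
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=1))


def trajectories_to_frame(trajs: list[Trajectory],
                          pop_size: int | None = None) -> pd.DataFrame:
    """Long-format records, one row per (trial, record, genotype, phenotype)."""
    rows = []
    for traj in trajs:
        G, P = traj.shape
        counts = (np.rint(traj.freqs * pop_size).astype(np.int64)
                  if pop_size is not None else None)
        for t in range(traj.n_records):
            for g in range(G):
                for p in range(P):
                    rows.append((
                        traj.trial, int(traj.dilutions[t]),
                        float(traj.times[t]), g, p,
                        int(counts[t, g, p]) if counts is not None else np.nan,
                        float(traj.freqs[t, g, p]),
                        float(traj.mean_fitness[t])))
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_trajectories(trajs: list[Trajectory], path: str | Path,
                       model: PrGPModel | None = None,
                       metadata: dict | None = None) -> None:
    """TSV writer plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    pop = model.pop_size if model is not None else None
    if trajs and trajs[0].trial == "ode":
        pop = None
    df = trajectories_to_frame(trajs, pop_size=pop)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {"n_trajectories": len(trajs),
            "dt": trajs[0].dt if trajs else None,
            "seed": trajs[0].seed if trajs else None}
    if model is not None:
        meta["model_hash"] = model.hash()
        meta["N"] = model.pop_size
    if metadata:
        meta.update(metadata)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Inverse of :func:`write_trajectories` (frequencies exact)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed trajectory file {path}: {exc}") from exc
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return []
    meta_path = Path(str(path) + ".meta.json")
    meta = (json.loads(meta_path.read_text()) if meta_path.exists() else {})
    out = []
    for trial, sub in df.groupby("trial", sort=False):
        G = int(sub["genotype"].max()) + 1
        P = int(sub["phenotype"].max()) + 1
        sub = sub.sort_values(["dilution", "genotype", "phenotype"])
        n_rec = sub["dilution"].nunique()
        freqs = sub["frequency"].to_numpy().reshape(n_rec, G, P)
        times = sub["time"].to_numpy().reshape(n_rec, G, P)[:, 0, 0]
        dil = sub["dilution"].to_numpy().reshape(n_rec, G, P)[:, 0, 0]
        xbar = sub["mean_fitness"].to_numpy().reshape(n_rec, G, P)[:, 0, 0]
        try:
            trial_id: int | str = int(trial)
        except (TypeError, ValueError):
            trial_id = str(trial)
        out.append(Trajectory(times=times, freqs=freqs, mean_fitness=xbar,
                              dilutions=dil, trial=trial_id,
                              seed=meta.get("seed"), dt=meta.get("dt")))
    return out
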