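"""Configuration loading, result serialisation and run manifests.

Configuration files are flat TOML: top-level keys are the parameter
symbols (``I``, ``U``, ``Sl``, ``Tp``, ``R``, ``Sp``, ``D``, ``v``,
``pi``, ``eps``, ``xi`` and, for the tripartite game, ``Tg``, ``F``,
``A``, ``phi``); an optional ``[simulation]`` table carries numerical
settings (``sigma``, ``h``, ``steps``, ``seed``, ``mode``, ``form``,
``shared_noise``).  Unknown keys are rejected.

Floats are serialised with 17 significant digits everywhere so that
written trajectories and configs round-trip bit-faithfully.
"""

from __future__ import annotations

import csv
import datetime
import json
import tomllib
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np

from .dynamics import Trajectory
from .errors import ConfigurationError
from .params import ParameterSet, validate_parameters
from .state import GameState
from .stochastic import EnsembleSummary, SimulationSettings

__all__ = [
    "load_config",
    "save_config",
    "baseline_parameters",
    "baseline_config_path",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_ensemble_json",
    "RunManifest",
    "build_manifest",
    "write_manifest",
]

_SIM_KEYS = {"sigma", "h", "steps", "seed", "mode", "form", "shared_noise"}


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def load_config(
    path: str | Path, model: str = "two"
) -> tuple[ParameterSet, SimulationSettings]:
    """Parse a TOML config into a parameter set and simulation settings.

    Missing ``[simulation]`` keys fall back to the package defaults.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigurationError(f"could not parse config {path}: {exc}") from exc

    sim_table = doc.pop("simulation", {})
    if not isinstance(sim_table, dict):
        raise ConfigurationError("[simulation] must be a table")
    unknown = set(sim_table) - _SIM_KEYS
    if unknown:
        raise ConfigurationError(
            "unknown simulation key(s): " + ", ".join(sorted(unknown))
        )
    for key, value in doc.items():
        if isinstance(value, dict):
            raise ConfigurationError(f"unknown table {key!r} in config")
    params = validate_parameters(doc, model=model)
    settings = SimulationSettings(**sim_table)
    return params, settings


def save_config(
    params: ParameterSet,
    path: str | Path,
    settings: SimulationSettings | None = None,
) -> None:
    """Write a parameter set (and optional settings) as flat TOML."""
    lines = [f"{key} = {_fmt(value)}" for key, value in params.to_dict().items()]
    if settings is not None:
        lines += ["", "[simulation]"]
        for key, value in asdict(settings).items():
            if value is None:
                continue
            if isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            elif isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            elif isinstance(value, int):
                lines.append(f"{key} = {value}")
            else:
                lines.append(f"{key} = {_fmt(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def baseline_config_path(model: str) -> Path:
    """Path of the packaged baseline config for ``model`` ("two"/"three")."""
    if model not in ("two", "three"):
        raise ConfigurationError(f"model must be 'two' or 'three', got {model!r}")
    name = f"baseline_{model}.toml"
    return Path(resources.files("cmcgame.data").joinpath(name))


def baseline_parameters(model: str) -> ParameterSet:
    """The packaged baseline parameter set for ``model``."""
    params, _ = load_config(baseline_config_path(model), model=model)
    return params


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV with header ``step,t,x,y,z``.

    The z column is left empty for two-subject runs.
    """
    states = trajectory.states
    tripartite = states.shape[1] == 3
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "t", "x", "y", "z"])
        for n, (t, row) in enumerate(zip(trajectory.times, states)):
            record = [n, _fmt(t), _fmt(row[0]), _fmt(row[1])]
            record.append(_fmt(row[2]) if tripartite else "")
            writer.writerow(record)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Re-parse a trajectory CSV written by :func:`write_trajectory_csv`.

    Settings are not stored in the CSV, so the returned trajectory has
    ``settings=None``.
    """
    times: list[float] = []
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rec in reader:
            times.append(float(rec["t"]))
            row = [float(rec["x"]), float(rec["y"])]
            if rec.get("z"):
                row.append(float(rec["z"]))
            rows.append(row)
    return Trajectory(
        times=np.asarray(times), states=np.asarray(rows), settings=None
    )


def write_ensemble_json(
    summary: EnsembleSummary, path: str | Path, base_seed: int | None = None
) -> None:
    """Serialise an ensemble summary (fractions, mean terminal, seeds)."""
    doc = {
        "replicates": summary.replicates,
        "base_seed": base_seed if base_seed is not None else summary.seeds[0],
        "seeds": summary.seeds,
        "convergence_fraction": summary.convergence_fraction,
        "mean_terminal": [float(v) for v in summary.mean_terminal],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunManifest:
    """Record of everything needed to reproduce a run bit-for-bit."""

    command: str
    model: str
    parameters: dict
    settings: dict
    state0: tuple
    seeds: list
    version: str
    timestamp: str
    extra: dict


def build_manifest(
    command: str,
    params: ParameterSet,
    settings: SimulationSettings,
    state0: GameState,
    seeds: list[int] | None = None,
    **extra,
) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        model="three" if state0.dims == 3 else "two",
        parameters=params.to_dict(),
        settings=asdict(settings),
        state0=state0.as_tuple(),
        seeds=seeds if seeds is not None else ([settings.seed] if settings.seed is not None else []),
        version=__version__,
        timestamp=datetime.datetime.now(datetime.UTC).isoformat(),
        extra=extra,
    )


def write_manifest(manifest: RunManifest, out_path: str | Path) -> Path:
    """Write ``manifest`` next to ``out_path`` as ``<out>.manifest.json``."""
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(asdict(manifest), indent=2, default=str) + "\n")
    return path
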