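"""Configuration, mesh snapshots, checkpoints, observable logs, phase scans.

Meshes are written as ASCII OFF or PLY with the per-face phase label sigma
as an integer face property (PLY: ``property int sigma``; OFF: one trailing
integer per face row).  Checkpoints are HDF5 containers holding the full
surface, the tuned move radius, the counters and the master RNG state, so a
resumed run reproduces the uninterrupted one.  Every output artifact
carries the config hash and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from . import observables as obs
from .energy import MODEL1, MODEL2, ModelParams
from .mc import MCState, RunSchedule, run
from .mesh import TriSurface

__all__ = [
    "ConfigError",
    "RunConfig",
    "ScanSpec",
    "load_config",
    "config_hash",
    "write_snapshot",
    "read_snapshot",
    "save_checkpoint",
    "load_checkpoint",
    "write_observables",
    "scan",
]


class ConfigError(ValueError):
    """A named configuration problem (unknown key, out-of-range value)."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    params: ModelParams
    schedule: RunSchedule
    subdivision: int
    mean_bond_length: Optional[float] = None  # None: scale-matched default
    output_dir: Optional[str] = None


@dataclasses.dataclass(frozen=True)
class ScanSpec:
    """A seeded grid of independent runs over one or two parameter axes."""

    base: RunConfig
    axes: dict[str, tuple[float, ...]]  # e.g. {"lambda": (...), "phi0": (...)}

    _AXIS_NAMES = ("lambda", "kappa", "c", "phi0")

    def points(self) -> list[dict[str, float]]:
        names = list(self.axes)
        grids = np.meshgrid(*[self.axes[n] for n in names], indexing="ij")
        return [{n: float(g.flat[i]) for n, g in zip(names, grids)}
                for i in range(grids[0].size)]


# ---------------------------------------------------------------------------
# config parsing
# ---------------------------------------------------------------------------

_SCHEMA = {
    "lattice": {"subdivision", "mean_bond_length"},
    "model": {"variant", "lambda", "kappa", "c", "phi0"},
    "schedule": {"thermalization", "measurement", "measure_interval",
                 "tuning_interval", "checkpoint_interval", "seed"},
    "output": {"dir"},
    "scan": {"axes"},
}


def _check_keys(section: str, mapping: dict) -> None:
    unknown = set(mapping) - _SCHEMA[section]
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")


def load_config(path: Union[str, pathlib.Path]) -> Union[RunConfig, ScanSpec]:
    """Parse and validate a YAML config; canonicalized (c >= 1) parameters.

    A ``scan`` section turns the file into a :class:`ScanSpec` whose other
    sections define the base run at each grid point.
    """
    path = pathlib.Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"{path}: unknown section(s) {sorted(unknown)}")
    for sec in ("lattice", "model", "schedule"):
        if sec not in raw:
            raise ConfigError(f"{path}: missing section '{sec}'")
        if not isinstance(raw[sec], dict):
            raise ConfigError(f"{path}: section '{sec}' must be a mapping")
        _check_keys(sec, raw[sec])

    lat = raw["lattice"]
    subdivision = int(lat.get("subdivision", 0))
    if subdivision < 1:
        raise ConfigError("lattice.subdivision must be a positive integer")
    mean_bond_length = lat.get("mean_bond_length")
    if mean_bond_length is not None:
        mean_bond_length = float(mean_bond_length)
        if mean_bond_length <= 0:
            raise ConfigError("lattice.mean_bond_length must be > 0")

    mod = raw["model"]
    variant = str(mod.get("variant", MODEL2)).lower()
    if variant in ("1", "model 1"):
        variant = MODEL1
    if variant in ("2", "model 2"):
        variant = MODEL2
    try:
        params = ModelParams(lambda_=float(mod.get("lambda", 0.0)),
                             kappa=float(mod.get("kappa", 1.0)),
                             c=float(mod.get("c", 1.0)),
                             phi0=float(mod.get("phi0", 0.5)),
                             variant=variant)
    except ValueError as exc:
        raise ConfigError(f"model: {exc}") from exc

    sch = raw["schedule"]
    try:
        schedule = RunSchedule(
            thermalization=int(sch.get("thermalization", 0)),
            measurement=int(sch.get("measurement", 0)),
            measure_interval=int(sch.get("measure_interval", 100)),
            tuning_interval=int(sch.get("tuning_interval", 500)),
            checkpoint_interval=(int(sch["checkpoint_interval"])
                                 if sch.get("checkpoint_interval") else None),
            seed=int(sch.get("seed", 0)))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"schedule: {exc}") from exc

    out = raw.get("output") or {}
    if out:
        _check_keys("output", out)
    cfg = RunConfig(params=params, schedule=schedule, subdivision=subdivision,
                    mean_bond_length=mean_bond_length,
                    output_dir=out.get("dir"))

    if "scan" in raw:
        scan_sec = raw["scan"] or {}
        _check_keys("scan", scan_sec)
        axes_raw = scan_sec.get("axes") or {}
        if not axes_raw or len(axes_raw) > 2:
            raise ConfigError("scan.axes must map 1 or 2 parameter names to value lists")
        axes = {}
        for name, values in axes_raw.items():
            if name not in ScanSpec._AXIS_NAMES:
                raise ConfigError(f"scan axis '{name}' not one of {ScanSpec._AXIS_NAMES}")
            axes[name] = tuple(float(v) for v in values)
        return ScanSpec(base=cfg, axes=axes)
    return cfg


def config_hash(cfg: Union[RunConfig, ScanSpec]) -> str:
    """Short stable hash of the canonicalized configuration."""
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# mesh snapshots
# ---------------------------------------------------------------------------

def write_snapshot(surface: TriSurface, path: Union[str, pathlib.Path],
                   fmt: Optional[str] = None) -> pathlib.Path:
    """Write an ASCII OFF/PLY snapshot with per-face sigma; format from suffix."""
    path = pathlib.Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in ("off", "ply"):
        raise ValueError(f"format must be 'off' or 'ply', got {fmt!r}")
    n, nt, nb = surface.n_vertices, surface.n_triangles, surface.n_bonds
    try:
        with open(path, "w") as fh:
            if fmt == "off":
                fh.write("OFF\n")
                fh.write(f"{n} {nt} {nb}\n")
                for x, y, z in surface.pos:
                    fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
                for (a, b, c), s in zip(surface.tri, surface.sigma):
                    fh.write(f"3 {a} {b} {c} {s}\n")
            else:
                fh.write("ply\nformat ascii 1.0\n")
                fh.write(f"element vertex {n}\n")
                fh.write("property double x\nproperty double y\nproperty double z\n")
                fh.write(f"element face {nt}\n")
                fh.write("property list uchar int vertex_indices\n")
                fh.write("property int sigma\nend_header\n")
                for x, y, z in surface.pos:
                    fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
                for (a, b, c), s in zip(surface.tri, surface.sigma):
                    fh.write(f"3 {a} {b} {c} {s}\n")
    except OSError as exc:
        raise OSError(f"cannot write snapshot {path}: {exc}") from exc
    return path


def read_snapshot(path: Union[str, pathlib.Path]) -> TriSurface:
    """Read a snapshot written by :func:`write_snapshot` (OFF or PLY)."""
    path = pathlib.Path(path)
    try:
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
    except OSError as exc:
        raise OSError(f"cannot read snapshot {path}: {exc}") from exc
    if lines[0] == "OFF":
        n, nt, _ = (int(x) for x in lines[1].split())
        body = lines[2:]
    elif lines[0] == "ply":
        n = nt = 0
        i = 1
        while lines[i] != "end_header":
            parts = lines[i].split()
            if parts[:2] == ["element", "vertex"]:
                n = int(parts[2])
            elif parts[:2] == ["element", "face"]:
                nt = int(parts[2])
            i += 1
        body = lines[i + 1:]
    else:
        raise ValueError(f"{path}: not an OFF or PLY snapshot")
    pos = np.array([[float(x) for x in body[i].split()] for i in range(n)])
    tri = np.empty((nt, 3), dtype=np.int64)
    sigma = np.empty(nt, dtype=np.int64)
    for i in range(nt):
        parts = body[n + i].split()
        if parts[0] != "3":
            raise ValueError(f"{path}: non-triangular face")
        tri[i] = [int(parts[1]), int(parts[2]), int(parts[3])]
        sigma[i] = int(parts[4])
    return TriSurface.from_triangles(pos, tri, sigma)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: MCState, path: Union[str, pathlib.Path],
                    meta: Optional[dict] = None) -> pathlib.Path:
    path = pathlib.Path(path)
    s = state.surface
    with h5py.File(path, "w") as h5:
        # all tables verbatim: rebuilding adjacency would permute bond ids
        # and change the RNG-to-bond mapping, breaking exact resumption
        for field in dataclasses.fields(TriSurface):
            h5.create_dataset(field.name, data=getattr(s, field.name))
        h5.attrs["move_radius"] = state.move_radius
        h5.attrs["sweep"] = state.sweep
        h5.attrs["vertex_accepted"] = state.vertex_accepted
        h5.attrs["vertex_attempted"] = state.vertex_attempted
        h5.attrs["flip_accepted"] = state.flip_accepted
        h5.attrs["flip_attempted"] = state.flip_attempted
        h5.attrs["params"] = json.dumps(dataclasses.asdict(state.params))
        h5.attrs["rng_state"] = json.dumps(state.rng.bit_generator.state)
        if meta:
            h5.attrs["meta"] = json.dumps(meta)
    return path


def load_checkpoint(path: Union[str, pathlib.Path]) -> MCState:
    path = pathlib.Path(path)
    with h5py.File(path, "r") as h5:
        surface = TriSurface(*(np.ascontiguousarray(h5[f.name][...])
                               for f in dataclasses.fields(TriSurface)))
        surface.validate()
        params = ModelParams(**json.loads(h5.attrs["params"]))
        rng = np.random.default_rng()
        rng.bit_generator.state = json.loads(h5.attrs["rng_state"])
        state = MCState(surface=surface, params=params,
                        move_radius=float(h5.attrs["move_radius"]), rng=rng,
                        sweep=int(h5.attrs["sweep"]),
                        vertex_accepted=int(h5.attrs["vertex_accepted"]),
                        vertex_attempted=int(h5.attrs["vertex_attempted"]),
                        flip_accepted=int(h5.attrs["flip_accepted"]),
                        flip_attempted=int(h5.attrs["flip_attempted"]))
    state.recompute_energy()
    return state


# ---------------------------------------------------------------------------
# observable logs and scans
# ---------------------------------------------------------------------------

def write_observables(df: pd.DataFrame, path: Union[str, pathlib.Path],
                      cfg: Optional[Union[RunConfig, ScanSpec]] = None,
                      seed: Optional[int] = None) -> pathlib.Path:
    """TSV log with provenance header lines (# config_hash, # seed)."""
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        if cfg is not None:
            fh.write(f"# config_hash={config_hash(cfg)}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_observables(path: Union[str, pathlib.Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


_AXIS_TO_FIELD = {"lambda": "lambda_", "kappa": "kappa", "c": "c", "phi0": "phi0"}


def _point_params(base: ModelParams, point: dict[str, float]) -> ModelParams:
    kwargs = {f.name: getattr(base, f.name) for f in dataclasses.fields(base)}
    for axis, value in point.items():
        kwargs[_AXIS_TO_FIELD[axis]] = value
    return ModelParams(**kwargs)


def scan(spec: ScanSpec, out_path: Optional[Union[str, pathlib.Path]] = None,
         ) -> pd.DataFrame:
    """Run every grid point independently (seeded) and tabulate the means.

    Each point gets a unique seed derived from the base seed.  If
    ``out_path`` already holds rows for some points they are kept and those
    points skipped, so an interrupted scan can be resumed; per-point
    failures are recorded and the scan continues.
    """
    done: set[tuple] = set()
    old_rows: list[dict] = []
    if out_path is not None and pathlib.Path(out_path).exists():
        old = read_observables(out_path)
        axis_cols = list(spec.axes)
        old_rows = old.to_dict("records")
        done = {tuple(round(float(r[a]), 12) for a in axis_cols) for r in old_rows}

    rows = list(old_rows)
    base_seed = spec.base.schedule.seed
    for idx, point in enumerate(spec.points()):
        key = tuple(round(v, 12) for v in point.values())
        if key in done:
            continue
        seed = (base_seed * 100003 + 7919 * idx + 1) % (2**31 - 1)
        row: dict = dict(point)
        row["seed"] = seed
        try:
            params = _point_params(spec.base.params, point)
            schedule = dataclasses.replace(spec.base.schedule, seed=seed)
            df, state = run(params, schedule, spec.base.subdivision,
                            mean_bond_length=spec.base.mean_bond_length)
            stats = obs.domain_components(state.surface)
            label = obs.classify_morphology(stats, surface=state.surface)
            for col in ("s0", "s1_per_n", "s2_per_nb", "d1", "d2", "d3",
                        "boundary_bonds", "area_fraction_lo"):
                row[col] = float(df[col].mean())
            row["n_lo_components"] = stats.n_lo_components
            row["n_ld_components"] = stats.n_ld_components
            row["morphology"] = label.label
            row["error"] = ""
        except Exception as exc:  # record and continue with the next point
            row["morphology"] = "error"
            row["error"] = str(exc)
        rows.append(row)
        if out_path is not None:
            write_observables(pd.DataFrame(rows), out_path, cfg=spec,
                              seed=base_seed)
    return pd.DataFrame(rows)
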