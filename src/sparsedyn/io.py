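"""File formats, run configuration and task execution.

Trajectories travel as delimited text (header row, first column ``t``,
uniform spacing); field series as HDF5 with axis metadata; fit results as
JSON reports.  Every run emits a provenance block (config, seed, package
version) sufficient to regenerate the artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .library import FieldSeries, Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_field_series",
    "write_field_series",
    "RunConfig",
    "run",
]

_REL_TOL = 1e-9  # relative tolerance on time-grid uniformity


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write as delimited text at 17 significant digits (lossless round-trip)."""
    df = pd.DataFrame(traj.values, columns=list(traj.names))
    df.insert(0, "t", traj.times)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    if df.shape[0] < 2:
        raise ValueError("trajectory file must contain at least 2 rows")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    steps = np.diff(t)
    step = steps[0]
    bad = np.flatnonzero(np.abs(steps - step) > _REL_TOL * max(abs(step), 1e-300))
    if step <= 0 or len(bad):
        row = int(bad[0]) + 1 if len(bad) else 1
        raise ValueError(f"irregular time sampling at row {row} of {path}")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return Trajectory(values, step=float(step), t0=float(t[0]),
                      names=tuple(df.columns[1:]))


def write_field_series(fs: FieldSeries, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        for name, arr in fs.fields.items():
            h5.create_dataset(name, data=arr)
        h5.attrs["dx"] = fs.dx
        h5.attrs["dy"] = fs.dy if fs.dy is not None else np.nan
        h5.attrs["dt"] = fs.dt
        h5.attrs["t0"] = fs.t0
        h5.attrs["boundary"] = fs.boundary
        h5.attrs["meta"] = json.dumps(fs.meta, default=str)


def read_field_series(path: str | Path) -> FieldSeries:
    import h5py

    with h5py.File(path, "r") as h5:
        fields = {k: np.array(h5[k]) for k in h5.keys()}
        dy = float(h5.attrs["dy"])
        fs = FieldSeries(
            fields=fields,
            dx=float(h5.attrs["dx"]),
            dy=None if np.isnan(dy) else dy,
            dt=float(h5.attrs["dt"]),
            t0=float(h5.attrs["t0"]),
            boundary=str(h5.attrs["boundary"]),
            meta=json.loads(h5.attrs["meta"]),
        )
    return fs


_TASKS = ("simulate", "fit-ode", "fit-pde", "fit-sde", "aiso", "score")
_ALLOWED_KEYS = {
    "task", "model", "params", "library", "solver", "io", "seed",
    "n_steps", "dt", "x0", "noise_fraction", "mode", "bins", "filter",
    "p_star", "tsallis_q", "component", "n_iter", "steps_per_iter",
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline task."""

    task: str
    model: str | None = None
    params: dict = field(default_factory=dict)
    library: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    io: dict = field(default_factory=dict)
    seed: int = 0
    options: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        unknown = set(cfg) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        task = cfg.get("task")
        if task not in _TASKS:
            raise ValueError(f"config key 'task' must be one of {_TASKS}, got {task!r}")
        known = {k: cfg[k] for k in ("model", "params", "library", "solver", "io", "seed") if k in cfg}
        options = {k: v for k, v in cfg.items() if k not in known and k != "task"}
        return cls(task=task, options=options, **known)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def provenance(self) -> dict:
        blob = json.dumps(
            {"task": self.task, "model": self.model, "params": self.params,
             "library": self.library, "solver": self.solver,
             "seed": self.seed, "options": self.options},
            sort_keys=True, default=str,
        )
        return {
            "config": json.loads(blob),
            "config_sha1": hashlib.sha1(blob.encode()).hexdigest(),
            "seed": self.seed,
            "version": __version__,
        }


def _report(path: str | Path, payload: dict, provenance: dict) -> None:
    payload = dict(payload)
    payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def run(config: RunConfig) -> dict:
    """Execute one configured task; returns the report payload."""
    from . import active, fixtures, km, library, metrics
    from .atsbl import atsbl_fit
    from .terms import LibrarySpec

    prov = config.provenance()
    out = config.io.get("output", "report.json")
    solver = dict(config.solver)
    prior = solver.pop("prior", "laplace")

    if config.task == "simulate":
        model = fixtures.make_fixture(config.model, **config.params)
        traj = fixtures.euler_maruyama(
            model,
            x0=config.options.get("x0", [0.0] * model.n_components),
            dt=config.options.get("dt", 5e-3),
            n_steps=int(config.options.get("n_steps", 10_000)),
            seed=config.seed,
        )
        frac = config.options.get("noise_fraction", 0.0)
        if frac:
            traj.values = fixtures.add_noise(traj.values, frac, config.seed + 1)
        dest = config.io.get("trajectory", "trajectory.csv")
        write_trajectory(traj, dest)
        sidecar = {
            "model": config.model, "params": config.params,
            "n_steps": traj.n_samples - 1, "dt": traj.step,
        }
        _report(out, {"task": "simulate", "trajectory": str(dest), **sidecar}, prov)
        return sidecar

    if config.task == "fit-sde":
        traj = read_trajectory(config.io["trajectory"])
        drift_spec = (
            LibrarySpec.from_config(config.library["drift"])
            if "drift" in config.library
            else library.drift_library_1d()
        )
        diff_spec = (
            LibrarySpec.from_config(config.library["diffusion"])
            if "diffusion" in config.library
            else library.diffusion_library_1d()
        )
        est, report = km.fit_km(
            traj, drift_spec, diff_spec,
            mode=config.options.get("mode", "direct"),
            Q=int(config.options.get("bins", 200)),
            filter=bool(config.options.get("filter", True)),
            p_star=config.options.get("p_star"),
            tsallis_q=float(config.options.get("tsallis_q", 0.8)),
            prior=prior, seed=config.seed, **solver,
        )
        payload = {
            "task": "fit-sde",
            "drift": {"coefficients": est.drift_coeffs, "equations": [
                metrics.format_equation(c, target_name=f"D1_{n}")
                for c, n in zip(est.drift_coeffs, est.names)
            ]},
            "diffusion": {"coefficients": est.diff_coeffs},
            "mode": report.mode, "bins": report.Q, "p_star": report.p_star,
        }
        _report(out, payload, prov)
        return payload

    if config.task == "fit-ode":
        traj = read_trajectory(config.io["trajectory"])
        spec = (
            LibrarySpec.from_config(config.library)
            if config.library
            else library.polynomial_spec(traj.names, 4)
        )
        comp = config.options.get("component")
        comps = [comp] if comp is not None else list(traj.names)
        payload = {"task": "fit-ode", "equations": {}}
        for c in comps:
            system = library.build_ode_system(traj, spec, c)
            model, _ = atsbl_fit(system, prior=prior, seed=config.seed, **solver)
            payload["equations"][c] = {
                "coefficients": model.coefficients(),
                "formatted": metrics.format_equation(model, target_name=f"d{c}/dt"),
            }
        _report(out, payload, prov)
        return payload

    if config.task == "fit-pde":
        fs = read_field_series(config.io["fields"])
        spec = (
            LibrarySpec.from_config(config.library)
            if config.library
            else library.lambda_omega_library()
        )
        comp = config.options.get("component")
        comps = [comp] if comp is not None else list(fs.names)
        payload = {"task": "fit-pde", "equations": {}}
        for c in comps:
            system = library.build_pde_system(fs, spec, c, seed=config.seed)
            model, _ = atsbl_fit(system, prior=prior, seed=config.seed, **solver)
            payload["equations"][c] = {
                "coefficients": model.coefficients(),
                "formatted": metrics.format_equation(model, target_name=f"d{c}/dt"),
            }
        _report(out, payload, prov)
        return payload

    if config.task == "aiso":
        model = fixtures.make_fixture(config.model, **config.params)
        drift_spec = (
            LibrarySpec.from_config(config.library["drift"])
            if "drift" in config.library
            else library.drift_library_1d()
        )
        diff_spec = (
            LibrarySpec.from_config(config.library["diffusion"])
            if "diffusion" in config.library
            else library.diffusion_library_1d()
        )
        est, state = active.aiso(
            model, drift_spec, diff_spec,
            n_iter=int(config.options.get("n_iter", 10)),
            steps_per_iter=int(config.options.get("steps_per_iter", 100_000)),
            dt=float(config.options.get("dt", 5e-3)),
            seed=config.seed, prior=prior,
        )
        payload = {
            "task": "aiso",
            "drift": est.drift_coeffs,
            "diffusion": est.diff_coeffs,
            "dic_trace": state.dic_trace,
            "iterations": state.iteration,
        }
        _report(out, payload, prov)
        return payload

    if config.task == "score":
        with open(config.io["report"]) as fh:
            rep = json.load(fh)
        model = fixtures.make_fixture(config.model, **config.params)
        scores = {}
        drift = rep.get("drift", {}).get("coefficients") or rep.get("drift")
        diff = rep.get("diffusion", {}).get("coefficients") or rep.get("diffusion")
        for l, name in enumerate(model.names):
            if drift:
                scores[f"dic_drift_{name}"] = metrics.dic(
                    drift[l], model.drift_coeffs[l]
                )
            if diff:
                scores[f"dic_diffusion_{name}"] = metrics.dic(
                    diff[l], model.diff_coeffs[l]
                )
        payload = {"task": "score", "scores": scores}
        _report(out, payload, prov)
        return payload

    raise ValueError(f"unhandled task {config.task!r}")  # pragma: no cover
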