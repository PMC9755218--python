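"""Construction of regression targets and candidate-function design matrices.

Targets (time derivatives, or increment statistics provided by
:mod:`sparsedyn.km`) and library columns are always evaluated on the same
co-registered samples, so every row of a built :class:`LinearSystem` maps
back to a (time, space) sample of the input data.

Derivatives use the 4th-order central 5-point stencil.  On non-periodic axes
the outermost two samples per edge cannot be differenced at full order and
are excluded from the regression rows rather than handled with one-sided
stencils (which would lose accuracy order).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import savgol_filter

from .bayes_core import LinearSystem
from .terms import LibrarySpec, Monomial, Term, TimeModulated, polynomial_spec

__all__ = [
    "Trajectory",
    "FieldSeries",
    "finite_difference",
    "build_ode_system",
    "build_pde_system",
    "build_value_system",
    "build_time_modulated_library",
    "smooth_trajectory",
    "lorenz_library",
    "lambda_omega_library",
    "drift_library_1d",
    "diffusion_library_1d",
]

# 4th-order central stencils on 5 points
_D1 = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / 12.0
_D2 = np.array([-1.0, 16.0, -30.0, 16.0, -1.0]) / 12.0
_EDGE = 2


@dataclass
class Trajectory:
    """Regularly sampled M-component time series."""

    values: np.ndarray  # (N, M)
    step: float
    t0: float = 0.0
    names: tuple[str, ...] = ()
    control: np.ndarray | None = None  # (N-1, M) applied control, if simulated
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.values.shape[1] > 1 and not self.names:
            pass  # ambiguous single-row input is accepted as one sample
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not self.names:
            m = self.values.shape[1]
            self.names = ("x",) if m == 1 else tuple(f"x{i+1}" for i in range(m))
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names length does not match number of components")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.step * np.arange(self.n_samples)


@dataclass
class FieldSeries:
    """Space-time field snapshots on a regular grid (1 or 2 space dimensions)."""

    fields: dict[str, np.ndarray]  # name -> (T, Rx) or (T, Rx, Ry)
    dx: float
    dt: float
    dy: float | None = None
    boundary: str = "periodic"  # "periodic" | "open"
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {k: v.shape for k, v in self.fields.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"inconsistent field shapes: {shapes}")
        if self.boundary not in ("periodic", "open"):
            raise ValueError("boundary must be 'periodic' or 'open'")
        shape = next(iter(shapes.values()))
        if len(shape) == 3 and self.dy is None:
            self.dy = self.dx

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.fields)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.fields.values())).shape

    @property
    def n_snapshots(self) -> int:
        return self.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_snapshots)


def finite_difference(
    series: np.ndarray,
    step: float,
    order: int = 1,
    axis: int = 0,
    periodic: bool = False,
) -> np.ndarray:
    """4th-order central finite difference along ``axis``.

    Returns an array of the same shape.  For open boundaries the outermost
    two samples per edge are NaN (invalid; exclude them from regressions);
    periodic axes wrap instead.
    """
    a = np.asarray(series, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if a.shape[axis] < 5:
        raise ValueError(
            f"axis {axis} has {a.shape[axis]} samples; the 4th-order stencil needs >= 5"
        )
    stencil = _D1 if order == 1 else _D2
    h = step if order == 1 else step * step
    a = np.moveaxis(a, axis, 0)
    out = np.zeros_like(a)
    if periodic:
        for k, c in enumerate(stencil):
            if c != 0:
                out += c * np.roll(a, _EDGE - k, axis=0)
        out /= h
    else:
        for k, c in enumerate(stencil):
            if c != 0:
                out[_EDGE:-_EDGE] += c * a[k : a.shape[0] - (4 - k)]
        out /= h
        out[:_EDGE] = np.nan
        out[-_EDGE:] = np.nan
    return np.moveaxis(out, 0, axis)


def smooth_trajectory(
    traj: Trajectory, window: int = 251, polyorder: int = 4
) -> Trajectory:
    """Savitzky–Golay smoothing of each component (noise suppression before
    finite differencing; the window must stay well below the fastest signal
    time scale)."""
    if window >= traj.n_samples:
        raise ValueError("smoothing window exceeds trajectory length")
    sm = savgol_filter(traj.values, window, polyorder, axis=0, mode="interp")
    out = Trajectory(sm, traj.step, traj.t0, traj.names, meta=dict(traj.meta))
    out.meta["smoothed"] = {"method": "savgol", "window": window, "polyorder": polyorder}
    return out


def build_value_system(
    data: Mapping[str, np.ndarray],
    spec: LibrarySpec,
    target: np.ndarray,
    valid: np.ndarray | None = None,
) -> LinearSystem:
    """Assemble a LinearSystem from aligned flat value arrays and a target."""
    target = np.asarray(target, dtype=float)
    if valid is not None:
        data = {k: np.asarray(v)[valid] for k, v in data.items()}
        target = target[valid]
    design = spec.evaluate(data)
    return LinearSystem(design, target, spec.names)


def build_ode_system(
    traj: Trajectory, spec: LibrarySpec, component: int | str
) -> LinearSystem:
    """Regression system  D_t z_ℓ = Θ(Z) ξ_ℓ  for one component ℓ."""
    if isinstance(component, str):
        component = traj.names.index(component)
    dz = finite_difference(traj.values[:, component], traj.step, order=1)
    valid = np.isfinite(dz)
    data = {name: traj.values[:, i] for i, name in enumerate(traj.names)}
    data["t"] = traj.times
    return build_value_system(data, spec, dz, valid)


def build_time_modulated_library(
    base_spec: LibrarySpec, omega: float
) -> LibrarySpec:
    """Double a library with cos(ωt)-modulated copies of every base term."""
    if not np.isfinite(omega):
        raise ValueError("omega must be finite")
    if omega == 0.0:
        warnings.warn(
            "omega = 0 makes modulated copies collinear with the originals",
            stacklevel=2,
        )
    modulated = tuple(TimeModulated(t, float(omega)) for t in base_spec.terms)
    return LibrarySpec(base_spec.variables, base_spec.terms + modulated)


def _spatial_derivatives(
    snap: np.ndarray, labels: tuple[str, ...], name: str, dx: float, dy: float | None,
    periodic: bool,
) -> dict[str, np.ndarray]:
    """Compute requested spatial-derivative fields of one snapshot."""
    out: dict[str, np.ndarray] = {}
    for lab in labels:
        if lab == f"lap_{name}":
            d = finite_difference(snap, dx, order=2, axis=0, periodic=periodic)
            if snap.ndim == 2:
                d = d + finite_difference(snap, dy, order=2, axis=1, periodic=periodic)
            out[lab] = d
            continue
        if not lab.startswith(f"{name}_"):
            continue
        suffix = lab[len(name) + 1 :]
        if suffix == "x":
            out[lab] = finite_difference(snap, dx, order=1, axis=0, periodic=periodic)
        elif suffix == "y":
            out[lab] = finite_difference(snap, dy, order=1, axis=1, periodic=periodic)
        elif suffix == "xx":
            out[lab] = finite_difference(snap, dx, order=2, axis=0, periodic=periodic)
        elif suffix == "yy":
            out[lab] = finite_difference(snap, dy, order=2, axis=1, periodic=periodic)
        elif suffix == "xy":
            d = finite_difference(snap, dx, order=1, axis=0, periodic=periodic)
            out[lab] = finite_difference(d, dy, order=1, axis=1, periodic=periodic)
        else:
            raise ValueError(f"unsupported derivative label {lab!r}")
    return out


def build_pde_system(
    fields: FieldSeries,
    spec: LibrarySpec,
    component: int | str,
    max_rows: int | None = 50_000,
    seed: int = 0,
) -> LinearSystem:
    """Regression system  D_t z_ℓ = Θ^P(Z^P, D_x Z^P, ...) ξ_ℓ.

    Rows are valid space-time samples; when there are more than ``max_rows``
    a uniform random subsample (seeded) is taken to keep regressions
    desk-scale.  Spatial derivatives are computed per retained time slice.
    """
    names = fields.names
    if isinstance(component, int):
        component = names[component]
    periodic = fields.boundary == "periodic"
    T = fields.n_snapshots
    if T < 5:
        raise ValueError("need at least 5 snapshots for the time derivative")
    t_valid = np.arange(_EDGE, T - _EDGE)
    space_shape = fields.shape[1:]
    n_space = int(np.prod(space_shape))
    total = len(t_valid) * n_space
    rng = np.random.default_rng(seed)
    if max_rows is not None and total > max_rows:
        flat_idx = np.sort(rng.choice(total, size=max_rows, replace=False))
    else:
        flat_idx = np.arange(total)
    t_of = t_valid[flat_idx // n_space]
    s_of = flat_idx % n_space

    deriv_labels = spec.derivative_labels
    comp_arr = fields.fields[component]
    dt = fields.dt

    rows_target: list[np.ndarray] = []
    rows_data: dict[str, list[np.ndarray]] = {
        name: [] for name in names
    }
    for lab in deriv_labels:
        rows_data[lab] = []
    rows_data["t"] = []

    times = fields.times
    for ti in np.unique(t_of):
        sel = s_of[t_of == ti]
        # 4th-order time derivative at slice ti from 5 neighbouring snapshots
        window = comp_arr[ti - 2 : ti + 3]
        dz = np.tensordot(_D1, window, axes=(0, 0)) / dt
        rows_target.append(dz.reshape(-1)[sel])
        for name in names:
            snap = fields.fields[name][ti]
            rows_data[name].append(snap.reshape(-1)[sel])
            labs = tuple(
                lab for lab in deriv_labels
                if lab == f"lap_{name}" or lab.startswith(f"{name}_")
            )
            dmap = _spatial_derivatives(snap, labs, name, fields.dx, fields.dy, periodic)
            for lab, arr in dmap.items():
                rows_data[lab].append(arr.reshape(-1)[sel])
        rows_data["t"].append(np.full(len(sel), times[ti]))

    target = np.concatenate(rows_target)
    data = {k: np.concatenate(v) for k, v in rows_data.items()}
    if not periodic:
        # drop rows whose spatial-derivative stencils touched an open edge
        mask = np.ones(len(target), dtype=bool)
        for k, v in data.items():
            mask &= np.isfinite(v)
        mask &= np.isfinite(target)
        data = {k: v[mask] for k, v in data.items()}
        target = target[mask]
    return build_value_system(data, spec, target)


# -- default library factories ----------------------------------------------


def lorenz_library(max_degree: int = 4) -> LibrarySpec:
    """Monomial library in (x, y, z) for chaotic-flow identification.

    Default total degree <= 4 (35 terms incl. the constant).  Degree 5 (56
    terms) is available but its condition number on attractor data is ~1e8,
    which makes the L0 penalty η = 1e-3 κ(Θ) large enough to swallow
    small true terms; see docs/methods.md.
    """
    return polynomial_spec(("x", "y", "z"), max_degree)


def drift_library_1d(max_degree: int = 10, trig: bool = False) -> LibrarySpec:
    """Default 11-term drift library for 1-D Langevin fits: monomials up to
    degree 10.

    ``trig=True`` appends sin(x) and cos(x).  They are off by default: on a
    symmetric sampled range of a few units, sin(x) is numerically inside the
    span of the odd monomials (its degree-7 remainder is percent-level), so
    trig terms make polynomial-drift libraries near-degenerate.
    """
    from .terms import Trig

    base = polynomial_spec(("x",), max_degree)
    if trig:
        return LibrarySpec(("x",), base.terms + (Trig("sin", "x"), Trig("cos", "x")))
    return base


def diffusion_library_1d() -> LibrarySpec:
    """Default 6-term diffusion library: monomials up to degree 5."""
    return polynomial_spec(("x",), 5)


def lambda_omega_library(include_laplacians: bool = False) -> LibrarySpec:
    """Default 31-term PDE library for two-component reaction-diffusion data:
    monomials in (u, v) to total degree 5 (21), second derivatives
    u_xx/u_yy/u_xy and v_xx/v_yy/v_xy (6) and first derivatives (4).

    An isotropic Laplacian appears as equal coefficients on the xx and yy
    derivatives.  Explicit ``lap_u``/``lap_v`` columns can be added, but they
    are exact sums of the xx and yy columns, which makes the design singular
    — keep them only if the separate second derivatives are removed.
    """
    from .terms import Derivative

    labels = [
        "u_xx", "u_yy", "u_xy", "v_xx", "v_yy", "v_xy",
        "u_x", "u_y", "v_x", "v_y",
    ]
    if include_laplacians:
        labels += ["lap_u", "lap_v"]
    poly = polynomial_spec(("u", "v"), 5)
    derivs = tuple(Derivative(lab) for lab in labels)
    return LibrarySpec(("u", "v"), poly.terms + derivs)
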