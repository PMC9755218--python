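"""Benchmark dynamical systems and synthetic-data generators.

Langevin models are simulated with the Euler–Maruyama scheme in the Itô
convention,

    X_{i+1} = X_i + [D¹(X_i, t_i) + c(X_i, t_i)] Δt + √(2 D²(X_i, t_i) Δt) ξ_i,

with ξ_i i.i.d. standard normal and c an optional external control force.
The built-in fixtures cover a bistable double-well drift with constant
diffusion, the same drift with space-dependent diffusion, a periodically
modulated double well, a three-well potential, and a planar (2-D) force
field; the Lorenz system and the λ–ω reaction–diffusion model provide ODE
and PDE benchmarks.  All generators are reproducible from an integer seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .library import FieldSeries, Trajectory
from .terms import (
    LibrarySpec,
    Monomial,
    Term,
    TimeModulated,
    Trig,
    parse_term,
)

__all__ = [
    "SDEModel",
    "LorenzParams",
    "RDParams",
    "SimulationBlowup",
    "euler_maruyama",
    "make_fixture",
    "integrate_lorenz",
    "solve_lambda_omega",
    "add_noise",
    "denoise",
    "compile_coeffs",
]

FIXTURE_NAMES = (
    "double_well",
    "time_dependent",
    "space_dep_diffusion",
    "three_well",
    "planar_field",
)


class SimulationBlowup(RuntimeError):
    def __init__(self, msg: str, last_valid: int):
        super().__init__(msg)
        self.last_valid = last_valid


def _scalar_term_fn(term: Term, variables: tuple[str, ...]):
    """Fast scalar evaluator f(x_seq, t) for a single library term."""
    if isinstance(term, Monomial):
        idx_pow = tuple((variables.index(v), p) for v, p in term.exponents)

        def f(x, t, _ip=idx_pow):
            out = 1.0
            for i, p in _ip:
                out *= x[i] ** p
            return out

        return f
    if isinstance(term, Trig):
        i = variables.index(term.var)
        fn = math.sin if term.kind == "sin" else math.cos
        return lambda x, t, _i=i, _f=fn: _f(x[_i])
    if isinstance(term, TimeModulated):
        base = _scalar_term_fn(term.base, variables)
        w = term.omega
        return lambda x, t, _b=base, _w=w: math.cos(_w * t) * _b(x, t)
    raise ValueError(f"term {term.name!r} cannot be evaluated in an SDE simulation")


def compile_coeffs(
    coeffs: dict[str, float],
    variables: Sequence[str],
    omega: float | None = None,
) -> Callable:
    """Compile a {term name: coefficient} map into a fast scalar callable.

    Pure 1-D polynomial parts (optionally cos(ωt)-modulated) are evaluated
    with Horner's rule; other terms fall back to per-term closures.
    """
    variables = tuple(variables)
    plain: list[tuple[Callable, float]] = []
    poly = None
    poly_mod = None
    if len(variables) == 1:
        base_deg: dict[int, float] = {}
        mod_deg: dict[int, float] = {}
        rest: dict[str, float] = {}
        for name, c in coeffs.items():
            term = parse_term(name, variables, omega=omega)
            tgt, t_inner = None, term
            if isinstance(term, TimeModulated):
                tgt, t_inner = mod_deg, term.base
            else:
                tgt = base_deg
            if isinstance(t_inner, Monomial):
                d = sum(p for _, p in t_inner.exponents)
                tgt[d] = tgt.get(d, 0.0) + c
            else:
                rest[name] = c
        if base_deg:
            poly = tuple(base_deg.get(d, 0.0) for d in range(max(base_deg) + 1))[::-1]
        if mod_deg:
            poly_mod = tuple(mod_deg.get(d, 0.0) for d in range(max(mod_deg) + 1))[::-1]
        coeffs = rest
    for name, c in coeffs.items():
        term = parse_term(name, variables, omega=omega)
        plain.append((_scalar_term_fn(term, variables), float(c)))

    def _horner(p, x):
        out = 0.0
        for a in p:
            out = out * x + a
        return out

    w = omega

    def f(x, t):
        tot = 0.0
        if poly is not None:
            tot += _horner(poly, x[0])
        if poly_mod is not None:
            tot += math.cos(w * t) * _horner(poly_mod, x[0])
        for fn, c in plain:
            tot += c * fn(x, t)
        return tot

    return f


@dataclass
class SDEModel:
    """Langevin model: per-component drift D¹ and (diagonal) diffusion D².

    ``drift_coeffs``/``diff_coeffs`` hold the defining {term name:
    coefficient} maps, which double as the reference for scoring fitted
    models; ``drift``/``diffusion`` are the compiled evaluators used by the
    simulator.
    """

    names: tuple[str, ...]
    drift_coeffs: tuple[dict[str, float], ...]
    diff_coeffs: tuple[dict[str, float], ...]
    params: dict = field(default_factory=dict)
    drift: tuple[Callable, ...] = ()
    diffusion: tuple[Callable, ...] = ()

    def __post_init__(self):
        omega = self.params.get("omega")
        if not self.drift:
            self.drift = tuple(
                compile_coeffs(c, self.names, omega) for c in self.drift_coeffs
            )
        if not self.diffusion:
            self.diffusion = tuple(
                compile_coeffs(c, self.names, omega) for c in self.diff_coeffs
            )

    @property
    def n_components(self) -> int:
        return len(self.names)

    @classmethod
    def from_coefficients(cls, names, drift_coeffs, diff_coeffs, params=None):
        return cls(
            names=tuple(names),
            drift_coeffs=tuple(dict(c) for c in drift_coeffs),
            diff_coeffs=tuple(dict(c) for c in diff_coeffs),
            params=dict(params or {}),
        )


def make_fixture(name: str, **overrides) -> SDEModel:
    """Return one of the built-in Langevin benchmark models.

    ``double_well``          D¹ = −2x³ + 12x² − 18x + 3,  D² = 0.8
    ``time_dependent``       D¹ = [a₀ + 1 − cos(ωt)]x − x³,  D² = 0.8
    ``space_dep_diffusion``  D¹ as double_well,  D² = x² − 2x + 2
    ``three_well``           D¹ = −6x⁵ + 24x³ − 1.5x² − 16x,  D² = 1
    ``planar_field``         2-D: radial + shear drift, D² = 1 per component

    Model parameters (a0, omega, b, diffusion constants) can be overridden
    by keyword.
    """
    if name == "double_well":
        d2 = overrides.get("d2", 0.8)
        return SDEModel.from_coefficients(
            ("x",),
            ({"1": 3.0, "x": -18.0, "x^2": 12.0, "x^3": -2.0},),
            ({"1": d2},),
        )
    if name == "time_dependent":
        a0 = overrides.get("a0", 5e-3)
        omega = overrides.get("omega", 0.05)
        d2 = overrides.get("d2", 0.8)
        return SDEModel.from_coefficients(
            ("x",),
            ({"x": a0 + 1.0, "x^3": -1.0, "cos(w t)*x": -1.0},),
            ({"1": d2},),
            params={"a0": a0, "omega": omega},
        )
    if name == "space_dep_diffusion":
        return SDEModel.from_coefficients(
            ("x",),
            ({"1": 3.0, "x": -18.0, "x^2": 12.0, "x^3": -2.0},),
            ({"1": 2.0, "x": -2.0, "x^2": 1.0},),
        )
    if name == "three_well":
        # drift = −dU/dx for U = x⁶ − 6x⁴ + 0.5x³ + 8x²
        d2 = overrides.get("d2", 1.0)
        return SDEModel.from_coefficients(
            ("x",),
            ({"x": -16.0, "x^2": -1.5, "x^3": 24.0, "x^5": -6.0},),
            ({"1": d2},),
        )
    if name == "planar_field":
        b = overrides.get("b", 1.0)
        d2 = overrides.get("d2", 1.0)
        dx = {"x": 1.0, "x^3": -1.0, "x*y^2": -1.0, "x^2*y": 1.0, "y^3": -1.0, "y": -b}
        dy = {"y": 1.0, "x^2*y": -1.0, "y^3": -1.0, "x^3": 1.0, "x*y^2": -1.0, "x": -b}
        return SDEModel.from_coefficients(
            ("x", "y"), (dx, dy), ({"1": d2}, {"1": d2}), params={"b": b}
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def euler_maruyama(
    model: SDEModel,
    x0: Sequence[float] | float,
    dt: float,
    n_steps: int,
    seed: int,
    control: Sequence[Callable] | None = None,
    t0: float = 0.0,
    bound: float = 1e8,
) -> Trajectory:
    """Simulate ``model`` for ``n_steps`` Euler–Maruyama steps.

    ``control`` is an optional per-component force c_ℓ(x, t) added to the
    drift; the applied values are recorded in ``Trajectory.control`` so that
    fits can subtract them from the increment statistics.  Raises
    :class:`SimulationBlowup` (with the last valid index) if the state
    leaves ``(-bound, bound)`` or becomes non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    M = model.n_components
    x0 = (float(x0),) if np.isscalar(x0) else tuple(float(v) for v in x0)
    if len(x0) != M:
        raise ValueError("x0 length does not match model dimension")
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal((n_steps, M))
    vals = np.empty((n_steps + 1, M))
    vals[0] = x0
    ctrl = np.zeros((n_steps, M))
    drift = model.drift
    diff = model.diffusion
    two_dt = 2.0 * dt
    x = x0
    comp = range(M)
    for i in range(n_steps):
        t = t0 + i * dt
        row = xi[i]
        new = []
        for l in comp:
            d2 = diff[l](x, t)
            if d2 <= 0:
                raise SimulationBlowup(
                    f"diffusion coefficient non-positive ({d2:g}) at step {i}", i
                )
            c = control[l](x, t) if control is not None else 0.0
            ctrl[i, l] = c
            new.append(x[l] + (drift[l](x, t) + c) * dt + math.sqrt(two_dt * d2) * row[l])
        ok = True
        for v in new:
            if not (-bound < v < bound):
                ok = False
        if not ok:
            raise SimulationBlowup(f"state diverged at step {i}", i)
        x = tuple(new)
        vals[i + 1] = new
    return Trajectory(
        vals,
        step=dt,
        t0=t0,
        names=model.names,
        control=ctrl if control is not None else None,
        meta={"seed": seed, "n_steps": n_steps, "dt": dt},
    )


@dataclass
class LorenzParams:
    a: float = 10.0
    b: float = 28.0
    c: float = 3.0 / 8.0  # as printed for this benchmark (canonical form uses 8/3)
    x0: tuple[float, float, float] = (-8.0, 8.0, 27.0)
    dt: float = 2e-4
    t_end: float = 25.0

    def __post_init__(self):
        if self.dt <= 0 or self.t_end <= self.dt:
            raise ValueError("require dt > 0 and t_end > dt")


def integrate_lorenz(p: LorenzParams | None = None) -> Trajectory:
    """Classic RK4 integration of the Lorenz system dx/dt = a(y−x),
    dy/dt = x(b−z) − y, dz/dt = xy − cz."""
    p = p or LorenzParams()
    a, b, c = p.a, p.b, p.c

    def rhs(x, y, z):
        return a * (y - x), x * (b - z) - y, x * y - c * z

    n = int(round(p.t_end / p.dt))
    vals = np.empty((n + 1, 3))
    x, y, z = p.x0
    vals[0] = (x, y, z)
    h = p.dt
    for i in range(n):
        k1 = rhs(x, y, z)
        k2 = rhs(x + 0.5 * h * k1[0], y + 0.5 * h * k1[1], z + 0.5 * h * k1[2])
        k3 = rhs(x + 0.5 * h * k2[0], y + 0.5 * h * k2[1], z + 0.5 * h * k2[2])
        k4 = rhs(x + h * k3[0], y + h * k3[1], z + h * k3[2])
        x += h * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
        y += h * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
        z += h * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]) / 6.0
        if not (abs(x) < 1e8 and abs(y) < 1e8 and abs(z) < 1e8):
            raise SimulationBlowup(f"Lorenz integration diverged at step {i}", i)
        vals[i + 1] = (x, y, z)
    return Trajectory(
        vals, step=p.dt, names=("x", "y", "z"),
        meta={"params": {"a": a, "b": b, "c": c}, "x0": list(p.x0)},
    )


@dataclass
class RDParams:
    """λ–ω reaction–diffusion parameters: ∂u/∂t = D_u ∇²u + λ(A)u − ω(A)v,
    ∂v/∂t = D_v ∇²v + ω(A)u + λ(A)v with A = u² + v², ω = −βA², λ = 1 − A²."""

    Du: float = 0.1
    Dv: float = 0.1
    beta_rd: float = 2.0
    L: float = 20.0
    n: int = 256
    dt: float = 0.0034
    t_end: float = 0.6


def _spiral_ic(p: RDParams) -> tuple[np.ndarray, np.ndarray]:
    ax = np.linspace(-p.L / 2, p.L / 2, p.n, endpoint=False)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2)
    th = np.arctan2(Y, X)
    return np.tanh(r) * np.cos(th - r), np.tanh(r) * np.sin(th - r)


def solve_lambda_omega(
    p: RDParams | None = None,
    ic: str = "spiral",
    seed: int = 0,
    stride: int = 1,
    burn_in: float = 3.0,
) -> FieldSeries:
    """Pseudo-spectral solution on a periodic square grid.

    Diffusion terms are evaluated spectrally (FFT Laplacian); the reaction
    terms are advanced explicitly with classic RK4.  Snapshots are stored
    every ``stride`` steps.

    The spiral initial pattern is not periodic-smooth (its phase has seams
    at the domain edges), which leaves sharp features that finite
    differences cannot resolve; ``burn_in`` time units (not recorded) are
    integrated first so that diffusion smooths these transients before the
    snapshot window starts.  Set ``burn_in=0`` to record from t=0.
    """
    p = p or RDParams()
    n = p.n
    dx = p.L / n
    k = 2 * np.pi * np.fft.fftfreq(n, d=dx)
    kx, ky = np.meshgrid(k, k, indexing="ij")
    k2 = kx**2 + ky**2
    cfl = max(p.Du, p.Dv) * float(k2.max()) * p.dt
    if cfl > 2.7:  # RK4 real-axis stability limit ~2.79
        warnings.warn(
            f"diffusion CFL number {cfl:.2f} exceeds the RK4 stability limit",
            stacklevel=2,
        )
    if ic == "spiral":
        u, v = _spiral_ic(p)
    elif ic == "random":
        rng = np.random.default_rng(seed)
        u = rng.standard_normal((n, n))
        v = rng.standard_normal((n, n))
        low = np.exp(-k2 / (2 * (2 * np.pi / p.L * 4) ** 2))
        u = np.fft.ifft2(np.fft.fft2(u) * low).real
        v = np.fft.ifft2(np.fft.fft2(v) * low).real
    else:
        raise ValueError("ic must be 'spiral' or 'random'")

    beta = p.beta_rd

    def lap(f):
        return np.fft.ifft2(-k2 * np.fft.fft2(f)).real

    def rhs(u, v):
        A2 = (u * u + v * v) ** 2
        du = p.Du * lap(u) + u - A2 * u + beta * A2 * v
        dv = p.Dv * lap(v) + v - A2 * v - beta * A2 * u
        return du, dv

    h = p.dt
    for i in range(int(round(burn_in / p.dt))):
        k1u, k1v = rhs(u, v)
        k2u, k2v = rhs(u + 0.5 * h * k1u, v + 0.5 * h * k1v)
        k3u, k3v = rhs(u + 0.5 * h * k2u, v + 0.5 * h * k2v)
        k4u, k4v = rhs(u + h * k3u, v + h * k3v)
        u = u + h * (k1u + 2 * k2u + 2 * k3u + k4u) / 6.0
        v = v + h * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0

    n_steps = int(round(p.t_end / p.dt))
    snaps_u = [u.copy()]
    snaps_v = [v.copy()]
    for i in range(n_steps):
        k1u, k1v = rhs(u, v)
        k2u, k2v = rhs(u + 0.5 * h * k1u, v + 0.5 * h * k1v)
        k3u, k3v = rhs(u + 0.5 * h * k2u, v + 0.5 * h * k2v)
        k4u, k4v = rhs(u + h * k3u, v + h * k3v)
        u = u + h * (k1u + 2 * k2u + 2 * k3u + k4u) / 6.0
        v = v + h * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
        if not np.all(np.isfinite(u)):
            raise SimulationBlowup(f"field solution diverged at step {i}", i)
        if (i + 1) % stride == 0:
            snaps_u.append(u.copy())
            snaps_v.append(v.copy())
    return FieldSeries(
        fields={"u": np.array(snaps_u), "v": np.array(snaps_v)},
        dx=dx,
        dy=dx,
        dt=p.dt * stride,
        boundary="periodic",
        meta={
            "model": "lambda_omega",
            "params": {
                "Du": p.Du, "Dv": p.Dv, "beta": beta, "L": p.L,
                "n": n, "dt": p.dt, "t_end": p.t_end,
            },
            "ic": ic,
            "seed": seed,
        },
    )


def add_noise(data: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Additive zero-mean Gaussian noise, per-coordinate σ = fraction × std.

    For a 2-D (samples × components) array the std is computed per column;
    otherwise a single std over the whole array is used.  Coordinates with
    zero variance are left unchanged.
    """
    if fraction < 0:
        raise ValueError("fraction must be nonnegative")
    data = np.asarray(data, dtype=float)
    if fraction == 0:
        return data.copy()
    rng = np.random.default_rng(seed)
    if data.ndim == 2:
        sd = data.std(axis=0)
    else:
        sd = data.std()
    return data + fraction * sd * rng.standard_normal(data.shape)


def _wavelet_shrink(snap: np.ndarray, wavelet: str, level: int | None) -> np.ndarray:
    import pywt

    coeffs = pywt.wavedec2(snap, wavelet, level=level, mode="periodization")
    detail = coeffs[-1][-1]
    sigma = np.median(np.abs(detail)) / 0.6745  # robust noise scale
    thr = sigma * math.sqrt(2.0 * math.log(snap.size))
    new = [coeffs[0]]
    for cs in coeffs[1:]:
        new.append(tuple(pywt.threshold(c, thr, mode="soft") for c in cs))
    return pywt.waverec2(new, wavelet, mode="periodization")[: snap.shape[0], : snap.shape[1]]


def denoise(series: FieldSeries, method: str = "spectral_lowpass", **params) -> FieldSeries:
    """Return a denoised copy of a field series.

    Methods: ``none``; ``gaussian_smooth`` (spatial Gaussian blur,
    ``sigma`` in pixels); ``wavelet_shrink`` (per-snapshot universal soft
    threshold, ``wavelet``/``level``); ``spectral_lowpass`` (keep spatial
    wavenumbers |k| <= ``frac`` × k_max).  Method and parameters are logged
    in the output metadata.
    """
    if method == "none":
        out_fields = {k: v.copy() for k, v in series.fields.items()}
    elif method == "gaussian_smooth":
        from scipy.ndimage import gaussian_filter

        sigma = params.get("sigma", 1.0)
        mode = "wrap" if series.boundary == "periodic" else "nearest"
        out_fields = {
            k: np.stack([gaussian_filter(s, sigma, mode=mode) for s in v])
            for k, v in series.fields.items()
        }
    elif method == "wavelet_shrink":
        wavelet = params.get("wavelet", "db4")
        level = params.get("level")
        out_fields = {
            k: np.stack([_wavelet_shrink(s, wavelet, level) for s in v])
            for k, v in series.fields.items()
        }
    elif method == "spectral_lowpass":
        frac = params.get("frac", 0.25)
        out_fields = {}
        for k, v in series.fields.items():
            T, nx = v.shape[0], v.shape[1]
            ny = v.shape[2] if v.ndim == 3 else 1
            kx = np.fft.fftfreq(nx)
            if v.ndim == 3:
                ky = np.fft.fftfreq(ny)
                KX, KY = np.meshgrid(kx, ky, indexing="ij")
                keep = np.sqrt(KX**2 + KY**2) <= frac * 0.5
                out_fields[k] = np.stack(
                    [np.fft.ifft2(np.fft.fft2(s) * keep).real for s in v]
                )
            else:
                keep = np.abs(kx) <= frac * 0.5
                out_fields[k] = np.stack(
                    [np.fft.ifft(np.fft.fft(s) * keep).real for s in v]
                )
    else:
        raise ValueError(f"unknown denoising method {method!r}")
    t_window = params.get("t_window")
    if t_window:
        # optional temporal smoothing stage: the fields evolve far below the
        # snapshot Nyquist rate, so a polynomial filter along t removes most
        # of the remaining noise without biasing the dynamics
        from scipy.signal import savgol_filter

        t_poly = params.get("t_polyorder", 4)
        out_fields = {
            k: savgol_filter(v, t_window, t_poly, axis=0, mode="interp")
            for k, v in out_fields.items()
        }
    meta = dict(series.meta)
    meta["denoise"] = {"method": method, **params}
    return FieldSeries(
        fields=out_fields,
        dx=series.dx,
        dy=series.dy,
        dt=series.dt,
        boundary=series.boundary,
        t0=series.t0,
        meta=meta,
    )
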