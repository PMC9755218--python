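"""Active learning of SDEs by adaptive control (AISO).

Trajectories of multistable Langevin systems stay trapped near single
energy minima, so a model fitted from one trajectory is only valid locally.
AISO escapes this by closing a feedback loop: after each sampling round the
drift is re-fitted from all data accumulated so far, and the next round is
simulated under a control force that locally *opposes* the inferred drift,

    c_ℓ(x, t) = −Θ_ℓ(x)·w_ℓ · exp[ −(x_ℓ − μ_ℓ)² / ζ_ℓ ],

where μ_ℓ and ζ_ℓ are the mean and variance of the previous round's
trajectory.  The Gaussian weight confines the perturbation to the region
already explored, flattening the local minimum and expelling the trajectory
toward unexplored phase space.  Because the applied control is known
exactly, it is subtracted from the drift increment statistics before each
fit, so the inference always targets the uncontrolled dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .atsbl import atsbl_fit
from .fixtures import SDEModel, SimulationBlowup, compile_coeffs, euler_maruyama
from .km import increments
from .library import Trajectory, build_value_system
from .metrics import dic
from .terms import LibrarySpec

__all__ = ["ControlState", "control_force", "trajectory_moments", "aiso"]

_ZETA_FLOOR_FRAC = 1e-6  # floor on ζ relative to the squared position range


@dataclass
class ControlState:
    """History of an AISO run."""

    iteration: int
    mu: np.ndarray  # (M,) latest trajectory means
    zeta: np.ndarray  # (M,) latest trajectory variances
    positions: np.ndarray  # accumulated (n, M)
    F1_raw: np.ndarray  # accumulated raw drift estimators (n, M)
    F2: np.ndarray  # accumulated diffusion estimators (n, M)
    controls: np.ndarray  # accumulated applied control values (n, M)
    times: np.ndarray  # accumulated sample times (n,)
    dic_trace: list[float] = field(default_factory=list)
    drift_history: list[tuple[dict, ...]] = field(default_factory=list)
    diff_history: list[tuple[dict, ...]] = field(default_factory=list)
    restarts: list[tuple[int, int]] = field(default_factory=list)  # (iteration, n_dampings)


def control_force(
    x: Sequence[float],
    t: float,
    weights: np.ndarray,
    spec: LibrarySpec,
    mu: Sequence[float],
    zeta: Sequence[float],
    component: int = 0,
) -> float:
    """Gaussian-weighted opposing force for one component at state (x, t)."""
    zeta_l = float(np.asarray(zeta).ravel()[component])
    if zeta_l <= 0:
        raise ValueError("zeta must be positive")
    mu_l = float(np.asarray(mu).ravel()[component])
    data = {v: np.asarray([xv], dtype=float) for v, xv in zip(spec.variables, x)}
    data["t"] = np.asarray([t], dtype=float)
    theta = spec.evaluate(data)[0]
    drift = float(theta @ np.asarray(weights, dtype=float))
    w = math.exp(-((x[component] - mu_l) ** 2) / zeta_l)
    return -drift * w


def trajectory_moments(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-component sample mean and population variance of a trajectory."""
    if traj.n_samples < 2:
        raise ValueError("need at least two samples")
    mu = traj.values.mean(axis=0)
    zeta = traj.values.var(axis=0)  # population convention
    return mu, zeta


class _GaussianControl:
    """Compiled per-component control  −Θ_ℓ(x)·w_ℓ exp[−(x_ℓ−μ_ℓ)²/ζ_ℓ]."""

    def __init__(self, drift_coeffs, names, mu, zeta, omega=None, damping=1.0):
        self.fns = [compile_coeffs(c, names, omega) for c in drift_coeffs]
        self.mu = [float(m) for m in mu]
        self.zeta = [float(z) for z in zeta]
        self.damping = damping

    def component(self, l: int) -> Callable:
        fn, mu, zeta, damp = self.fns[l], self.mu[l], self.zeta[l], self.damping

        def c(x, t):
            return -damp * fn(x, t) * math.exp(-((x[l] - mu) ** 2) / zeta)

        return c

    def forces(self, M: int):
        return [self.component(l) for l in range(M)]


def aiso(
    true_model: SDEModel,
    drift_spec: LibrarySpec,
    diff_spec: LibrarySpec,
    n_iter: int = 10,
    steps_per_iter: int = 100_000,
    dt: float = 5e-3,
    seed: int = 0,
    x0: Sequence[float] | float | None = None,
    prior: str = "laplace",
    n_iters_fit: int = 100,
    reference: SDEModel | None = None,
) -> tuple[SDEModel, ControlState]:
    """Automatic iterative sampling optimisation.

    Each iteration simulates ``steps_per_iter`` Euler–Maruyama steps of
    ``true_model`` (standing in for the experiment being probed) under the
    current control, appends the control-corrected increment statistics to
    the accumulated data, refits drift and diffusion with ATSBL on all data,
    and rebuilds the control from the newest drift estimate with μ, ζ taken
    from the latest trajectory only.  The first iteration is uncontrolled;
    each round starts from the final state of the previous one.  If a
    controlled simulation blows up, the control is damped by ½ and the
    round restarted.

    ``reference`` (defaulting to ``true_model``) provides the ground-truth
    coefficient maps for the per-iteration DIC trace.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    M = true_model.n_components
    names = true_model.names
    ref = reference if reference is not None else true_model
    omega = true_model.params.get("omega")

    if x0 is None:
        x0 = (0.0,) * M
    x_cur = (float(x0),) if np.isscalar(x0) else tuple(float(v) for v in x0)

    acc_pos: list[np.ndarray] = []
    acc_f1: list[np.ndarray] = []
    acc_f2: list[np.ndarray] = []
    acc_ctrl: list[np.ndarray] = []
    acc_t: list[np.ndarray] = []
    control = None
    est = None
    state = ControlState(
        iteration=0,
        mu=np.zeros(M),
        zeta=np.ones(M),
        positions=np.empty((0, M)),
        F1_raw=np.empty((0, M)),
        F2=np.empty((0, M)),
        controls=np.empty((0, M)),
        times=np.empty(0),
    )
    t_offset = 0.0

    for it in range(n_iter):
        forces = control.forces(M) if control is not None else None
        n_damp = 0
        while True:
            try:
                traj = euler_maruyama(
                    true_model,
                    x_cur,
                    dt,
                    steps_per_iter,
                    seed=seed * 1009 + it,
                    control=forces,
                    t0=t_offset,
                )
                break
            except SimulationBlowup:
                n_damp += 1
                if control is None or n_damp > 8:
                    raise
                control.damping *= 0.5
                forces = control.forces(M)
        if n_damp:
            state.restarts.append((it + 1, n_damp))
        x_cur = tuple(traj.values[-1])
        t_offset = traj.t0 + traj.step * steps_per_iter

        stats = increments(traj)
        acc_pos.append(stats.positions)
        acc_f1.append(stats.F1)
        acc_f2.append(stats.F2)
        acc_ctrl.append(traj.control if traj.control is not None else np.zeros_like(stats.F1))
        acc_t.append(stats.times)

        pos = np.concatenate(acc_pos)
        f1 = np.concatenate(acc_f1)
        f2 = np.concatenate(acc_f2)
        ctrl = np.concatenate(acc_ctrl)
        times = np.concatenate(acc_t)

        # fit on accumulated, control-corrected data
        data = {name: pos[:, i] for i, name in enumerate(names)}
        data["t"] = times
        drift_maps = []
        diff_maps = []
        for l in range(M):
            sys1 = build_value_system(data, drift_spec, f1[:, l] - ctrl[:, l])
            m1, _ = atsbl_fit(sys1, prior=prior, seed=seed, n_iters=n_iters_fit)
            sys2 = build_value_system(data, diff_spec, f2[:, l])
            m2, _ = atsbl_fit(sys2, prior=prior, seed=seed + 1, n_iters=n_iters_fit)
            drift_maps.append(m1.coefficients())
            diff_maps.append(m2.coefficients())
        est = SDEModel.from_coefficients(
            names, drift_maps, diff_maps,
            params={"omega": omega} if omega is not None else None,
        )
        state.drift_history.append(tuple(drift_maps))
        state.diff_history.append(tuple(diff_maps))

        if ref is not None:
            vals = []
            for l in range(M):
                vals.append(dic(drift_maps[l], ref.drift_coeffs[l]))
                vals.append(dic(diff_maps[l], ref.diff_coeffs[l]))
            state.dic_trace.append(float(np.mean(vals)))

        mu, zeta = trajectory_moments(traj)
        rng_span = traj.values.max(axis=0) - traj.values.min(axis=0)
        zeta = np.maximum(zeta, _ZETA_FLOOR_FRAC * np.maximum(rng_span, 1e-12) ** 2)
        state.mu, state.zeta = mu, zeta
        control = _GaussianControl(drift_maps, names, mu, zeta, omega=omega)
        state.iteration = it + 1

    state.positions = np.concatenate(acc_pos)
    state.F1_raw = np.concatenate(acc_f1)
    state.F2 = np.concatenate(acc_f2)
    state.controls = np.concatenate(acc_ctrl)
    state.times = np.concatenate(acc_t)
    return est, state
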