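"""Kramers–Moyal drift/diffusion estimation from sampled trajectories.

From a trajectory X_i sampled with step s, the finite-time estimators

    F¹_i = (X_{i+1} − X_i) / s          (drift,   units x/time)
    F²_i = (X_{i+1} − X_i)² / (2 s)     (diffusion, units x²/time)

fluctuate around D¹(X_i) and D²(X_i).  Sparse analytic forms of D¹ and D²
are obtained by regressing F¹ and F² on a function library evaluated either
directly at the trajectory positions, or (for 1-D data) at the centres of Q
equal-width bins after bin-averaging.  Sparsely populated bins can be
filtered out below an automatically determined probability threshold p*
(two-step Shannon/Tsallis class-entropy maximisation).

The O(s) contamination of F² by the squared drift is accepted; finite
sampling-time corrections are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atsbl import ThresholdState, atsbl_fit
from .bayes_core import LinearSystem, SparseModel
from .fixtures import SDEModel
from .library import Trajectory, build_value_system
from .terms import LibrarySpec

__all__ = [
    "IncrementStats",
    "BinnedStats",
    "FitReport",
    "increments",
    "bin_stats",
    "entropy_threshold",
    "fit_km",
]


@dataclass
class IncrementStats:
    """Per-sample drift/diffusion estimators F¹, F² aligned with positions."""

    F1: np.ndarray  # (N-1, M)
    F2: np.ndarray  # (N-1, M)
    positions: np.ndarray  # (N-1, M): X_i for i = 1..N-1
    times: np.ndarray  # (N-1,)
    step: float


@dataclass
class BinnedStats:
    """Bin-averaged increment statistics for a 1-D trajectory."""

    centers: np.ndarray  # (Q,)
    F1_bar: np.ndarray  # (Q,), NaN in empty bins
    F2_bar: np.ndarray
    probs: np.ndarray  # (Q,), sums to 1 over all bins
    counts: np.ndarray
    mask: np.ndarray  # retained bins (occupied, and above p* if filtered)
    p_star: float | None = None


@dataclass
class FitReport:
    """Details of a drift+diffusion library fit."""

    mode: str
    drift_fit: SparseModel
    diff_fit: SparseModel
    drift_state: ThresholdState
    diff_state: ThresholdState
    Q: int | None = None
    p_star: float | None = None
    n_rows: int = 0
    extras: dict = field(default_factory=dict)


def increments(traj: Trajectory) -> IncrementStats:
    """Exact evaluation of the F¹/F² increment sequences (Itô convention).

    If the trajectory records an applied control force, it is *not*
    subtracted here; see :func:`sparsedyn.active.aiso` for control-corrected
    fitting.
    """
    x = traj.values
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    s = traj.step
    dx = np.diff(x, axis=0)
    return IncrementStats(
        F1=dx / s,
        F2=dx**2 / (2.0 * s),
        positions=x[:-1],
        times=traj.times[:-1],
        step=s,
    )


def bin_stats(stats: IncrementStats, Q: int, component: int = 0) -> BinnedStats:
    """Group a 1-D trajectory into Q equal-width bins and average F¹/F²."""
    if Q < 2:
        raise ValueError("Q must be >= 2")
    x = stats.positions[:, component]
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("degenerate position range: min equals max")
    edges = np.linspace(lo, hi, Q + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, Q - 1)
    counts = np.bincount(idx, minlength=Q)
    sums1 = np.bincount(idx, weights=stats.F1[:, component], minlength=Q)
    sums2 = np.bincount(idx, weights=stats.F2[:, component], minlength=Q)
    with np.errstate(invalid="ignore", divide="ignore"):
        F1_bar = sums1 / counts
        F2_bar = sums2 / counts
    probs = counts / counts.sum()
    return BinnedStats(
        centers=centers,
        F1_bar=F1_bar,
        F2_bar=F2_bar,
        probs=probs,
        counts=counts,
        mask=counts > 0,
    )


def _class_shannon(p: np.ndarray) -> float:
    P = p.sum()
    if P <= 0:
        return 0.0
    q = p / P
    return float(-np.sum(q * np.log(q)))


def _class_tsallis(p: np.ndarray, q_idx: float) -> float:
    P = p.sum()
    if P <= 0:
        return 0.0
    r = p / P
    return float((1.0 - np.sum(r**q_idx)) / (q_idx - 1.0))


def entropy_threshold(probs: np.ndarray, q: float = 0.8) -> float:
    """Automatic probability threshold p* for bin filtering.

    Candidate thresholds are the midpoints between consecutive distinct bin
    probabilities.  Step 1 selects the candidate maximising the summed
    Shannon entropies of the below-/above-threshold classes (Kapur-style
    two-class criterion); step 2 refines the choice by maximising the
    two-class Tsallis criterion S_b + S_f + (1−q) S_b S_f with entropic
    index ``q``, breaking ties toward the Shannon optimum.  If all
    probabilities are equal, ``min(probs)`` is returned (no filtering).
    Bins with p_k >= p* are retained.
    """
    if q <= 0 or q == 1.0:
        raise ValueError("Tsallis index q must be positive and != 1")
    p = np.asarray(probs, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("no positive probabilities")
    levels = np.unique(p)
    if levels.size == 1:
        return float(levels[0])
    cands = 0.5 * (levels[:-1] + levels[1:])

    def shannon_score(c):
        return _class_shannon(p[p < c]) + _class_shannon(p[p >= c])

    def tsallis_score(c):
        sb = _class_tsallis(p[p < c], q)
        sf = _class_tsallis(p[p >= c], q)
        return sb + sf + (1.0 - q) * sb * sf

    sh = np.array([shannon_score(c) for c in cands])
    c_sh = cands[int(np.argmax(sh))]
    ts = np.array([tsallis_score(c) for c in cands])
    best = np.flatnonzero(ts >= ts.max() - 1e-12)
    c_star = cands[best[np.argmin(np.abs(cands[best] - c_sh))]]
    return float(c_star)


def fit_km(
    traj: Trajectory,
    drift_spec: LibrarySpec,
    diff_spec: LibrarySpec,
    mode: str = "direct",
    Q: int = 200,
    filter: bool = True,
    prior: str = "laplace",
    seed: int = 0,
    p_star: float | None = None,
    tsallis_q: float = 0.8,
    n_iters: int = 100,
    subtract_control: bool = False,
    **fit_kwargs,
) -> tuple[SDEModel, FitReport]:
    """Fit sparse analytic drift and diffusion coefficients to a trajectory.

    ``mode="direct"`` regresses F¹/F² on the library evaluated at the
    trajectory positions (any dimension); ``mode="binned"`` (1-D only)
    regresses the bin-averaged statistics on the library at the bin
    centres, optionally dropping bins with probability below p*
    (``filter=True``; ``p_star`` overrides the automatic threshold).
    ``subtract_control`` removes a recorded applied control force from F¹.
    """
    stats = increments(traj)
    M = traj.n_components
    names = traj.names
    F1 = stats.F1
    if subtract_control:
        if traj.control is None:
            raise ValueError("trajectory has no recorded control to subtract")
        F1 = F1 - traj.control
    if mode == "direct":
        data = {name: stats.positions[:, i] for i, name in enumerate(names)}
        data["t"] = stats.times
        drift_models, diff_models = [], []
        drift_states, diff_states = [], []
        n_rows = F1.shape[0]
        for l in range(M):
            sys1 = build_value_system(data, drift_spec, F1[:, l])
            m1, s1 = atsbl_fit(sys1, prior=prior, seed=seed, n_iters=n_iters, **fit_kwargs)
            sys2 = build_value_system(data, diff_spec, stats.F2[:, l])
            m2, s2 = atsbl_fit(sys2, prior=prior, seed=seed + 1, n_iters=n_iters, **fit_kwargs)
            drift_models.append(m1)
            diff_models.append(m2)
            drift_states.append(s1)
            diff_states.append(s2)
        p_used = None
        Q_used = None
    elif mode == "binned":
        if M != 1:
            raise ValueError("binned mode requires a one-dimensional trajectory")
        bs = bin_stats(stats, Q)
        mask = bs.mask.copy()
        p_used = None
        if filter:
            p_used = p_star if p_star is not None else entropy_threshold(
                bs.probs[bs.mask], q=tsallis_q
            )
            mask &= bs.probs >= p_used
        bs.mask = mask
        bs.p_star = p_used
        if not np.any(mask):
            raise ValueError(
                "no bins retained after probability filtering; "
                "reduce Q or disable the filter"
            )
        data = {names[0]: bs.centers[mask]}
        n_rows = int(mask.sum())
        sys1 = build_value_system(data, drift_spec, bs.F1_bar[mask])
        m1, s1 = atsbl_fit(sys1, prior=prior, seed=seed, n_iters=n_iters, **fit_kwargs)
        sys2 = build_value_system(data, diff_spec, bs.F2_bar[mask])
        m2, s2 = atsbl_fit(sys2, prior=prior, seed=seed + 1, n_iters=n_iters, **fit_kwargs)
        drift_models, diff_models = [m1], [m2]
        drift_states, diff_states = [s1], [s2]
        Q_used = Q
    else:
        raise ValueError("mode must be 'direct' or 'binned'")

    omega = next(
        (t.omega for t in drift_spec.terms if hasattr(t, "omega")), None
    )
    est = SDEModel.from_coefficients(
        names,
        tuple(m.coefficients() for m in drift_models),
        tuple(m.coefficients() for m in diff_models),
        params={"omega": omega} if omega is not None else None,
    )
    report = FitReport(
        mode=mode,
        drift_fit=drift_models[0] if M == 1 else drift_models,
        diff_fit=diff_models[0] if M == 1 else diff_models,
        drift_state=drift_states[0] if M == 1 else drift_states,
        diff_state=diff_states[0] if M == 1 else diff_states,
        Q=Q_used,
        p_star=p_used,
        n_rows=n_rows,
    )
    return est, report
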