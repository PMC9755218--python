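"""Kramers–Moyal increment statistics, binning and entropy filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsedyn import (
    Trajectory,
    atsbl_fit,
    bin_stats,
    entropy_threshold,
    fit_km,
    increments,
    make_fixture,
    polynomial_spec,
)
from sparsedyn.bayes_core import LinearSystem
from sparsedyn.fixtures import euler_maruyama
from sparsedyn.library import diffusion_library_1d, drift_library_1d


class TestIncrements:
    def test_hand_computed_identity(self):
        traj = Trajectory(np.array([[0.0], [0.1], [0.2]]), step=0.1)
        st_ = increments(traj)
        assert st_.F1[:, 0] == pytest.approx([1.0, 1.0])
        assert st_.F2[:, 0] == pytest.approx([0.05, 0.05])
        assert st_.positions[:, 0] == pytest.approx([0.0, 0.1])

    def test_constant_trajectory_zero(self):
        st_ = increments(Trajectory(np.full((10, 1), 2.0), step=0.5))
        assert np.all(st_.F1 == 0) and np.all(st_.F2 == 0)

    def test_random_identity_property(self, rng):
        x = rng.standard_normal(30).cumsum()
        s = 0.37
        st_ = increments(Trajectory(x[:, None], step=s))
        assert st_.F1[:, 0] == pytest.approx(np.diff(x) / s)
        assert st_.F2[:, 0] == pytest.approx(np.diff(x) ** 2 / (2 * s))

    def test_pure_diffusion_mean_matches_coefficient(self):
        # D1 = 0, D2 = c: ensemble mean of F2 estimates c; the estimator sd
        # is ~ sqrt(2) c per sample, so the sample-mean error is tiny at 1e5
        c = 0.6
        model = make_fixture("double_well")
        model = type(model).from_coefficients(("x",), ({},), ({"1": c},))
        traj = euler_maruyama(model, 0.0, 1e-3, 100_000, seed=4)
        st_ = increments(traj)
        se = np.sqrt(2.0) * c / np.sqrt(len(st_.F2))
        assert abs(st_.F2.mean() - c) < 3 * se


class TestBinning:
    def test_two_bins_probabilities_and_centers(self):
        traj = Trajectory(np.array([[0.0], [0.0], [1.0], [1.0], [1.0]]), step=1.0)
        bs = bin_stats(increments(traj), Q=2)
        assert bs.probs == pytest.approx([0.5, 0.5])
        assert bs.centers == pytest.approx([0.25, 0.75])

    def test_bin_mean_averages_members(self):
        vals = np.array([[0.0], [1.0], [0.1], [3.1]])  # F1 = 1/s, -0.9/s, 3/s
        traj = Trajectory(vals, step=1.0)
        st_ = increments(traj)
        bs = bin_stats(st_, Q=2)
        left = st_.F1[st_.positions[:, 0] <= 0.55, 0]
        assert bs.F1_bar[0] == pytest.approx(left.mean())

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bin_stats(increments(Trajectory(np.full((5, 1), 1.0), step=0.1)), Q=4)

    def test_binned_fit_consistent_with_direct_support(self):
        # the double-well benchmark with the standard 200-bin configuration:
        # the masked binned design yields the same drift support as the
        # direct fit on the same trajectory
        model = make_fixture("double_well")
        traj = euler_maruyama(model, 0.5, 5e-3, 200_000, seed=11)
        dl, fl = drift_library_1d(), diffusion_library_1d()
        est_d, _ = fit_km(traj, dl, fl, mode="direct", seed=0)
        est_b, rep = fit_km(traj, dl, fl, mode="binned", Q=200, filter=True, seed=0)
        assert rep.Q == 200
        assert set(est_b.drift_coeffs[0]) == set(est_d.drift_coeffs[0])


class TestEntropyThreshold:
    def test_two_level_distribution_split_between_levels(self, rng):
        lows = 0.001 + 1e-4 * rng.random(30)
        highs = 0.02 + 1e-3 * rng.random(20)
        p = np.concatenate([lows, highs])
        p = p / p.sum()
        p_star = entropy_threshold(p)
        assert p[p < p_star].max() < p_star < p[p >= p_star].min()
        # exhaustive-scan oracle: p* must separate the two generated classes
        assert (p < p_star).sum() == 30

    def test_uniform_probs_keep_everything(self):
        p = np.full(10, 0.1)
        assert entropy_threshold(p) == pytest.approx(0.1)

    def test_never_removes_most_probable_bin(self, rng):
        p = rng.random(50)
        p /= p.sum()
        assert entropy_threshold(p) <= p.max()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=1, max_value=20))
    def test_adding_near_zero_bins_never_drops_high_bins(self, n_extra):
        base = np.array([0.02, 0.021, 0.022, 0.018, 0.019, 0.001, 0.0012])
        extra = np.full(n_extra, 1e-5)
        p1 = base / base.sum()
        kept1 = {i for i in range(len(base)) if p1[i] >= entropy_threshold(p1)}
        p2 = np.concatenate([base, extra])
        p2 = p2 / p2.sum()
        p_star2 = entropy_threshold(p2)
        kept2 = {i for i in range(len(base)) if p2[i] >= p_star2}
        high = {i for i in range(len(base)) if base[i] > 0.01}
        assert high & kept1 <= kept2

    def test_invalid_tsallis_index_rejected(self):
        with pytest.raises(ValueError):
            entropy_threshold(np.array([0.5, 0.5]), q=1.0)


class TestFitKM:
    def test_manual_p_star_override(self):
        model = make_fixture("double_well")
        traj = euler_maruyama(model, 0.5, 5e-3, 50_000, seed=2)
        _, rep = fit_km(
            traj, drift_library_1d(), diffusion_library_1d(),
            mode="binned", Q=50, filter=True, p_star=1e-4, seed=0,
        )
        assert rep.p_star == pytest.approx(1e-4)

    def test_all_bins_filtered_raises(self):
        model = make_fixture("double_well")
        traj = euler_maruyama(model, 0.5, 5e-3, 5_000, seed=2)
        with pytest.raises(ValueError, match="retained"):
            fit_km(
                traj, drift_library_1d(), diffusion_library_1d(),
                mode="binned", Q=50, filter=True, p_star=1.1, seed=0,
            )

    def test_binned_requires_one_dimension(self):
        model = make_fixture("planar_field")
        traj = euler_maruyama(model, (0.1, 0.1), 5e-3, 2_000, seed=0)
        with pytest.raises(ValueError, match="one-dimensional"):
            fit_km(traj, polynomial_spec(("x", "y"), 3), polynomial_spec(("x", "y"), 2),
                   mode="binned", seed=0)

    @pytest.mark.parametrize(
        "fixture", ["double_well", "space_dep_diffusion", "three_well"]
    )
    def test_noise_free_representable_drift_target(self, fixture):
        # evaluate the generating drift exactly on a grid: the sparse fit
        # must recover exactly the generating terms (term-count invariant)
        model = make_fixture(fixture)
        x = np.linspace(-2.5, 4.0, 400)
        spec = drift_library_1d()
        design = spec.evaluate({"x": x})
        truth = model.drift_coeffs[0]
        g = sum(
            c * spec.evaluate({"x": x})[:, spec.names.index(k)] for k, c in truth.items()
        )
        m, _ = atsbl_fit(LinearSystem(design, g, spec.names), seed=0)
        assert set(m.coefficients()) == set(truth)
        assert m.coefficients() == pytest.approx(truth, abs=1e-6)
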