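"""Benchmark simulators: Euler–Maruyama, Lorenz, λ–ω, noise utilities."""

import numpy as np
import pytest
import sympy

from sparsedyn import (
    LorenzParams,
    RDParams,
    add_noise,
    denoise,
    euler_maruyama,
    integrate_lorenz,
    make_fixture,
    solve_lambda_omega,
)
from sparsedyn.fixtures import FIXTURE_NAMES, SDEModel, SimulationBlowup


class TestFixtures:
    @pytest.mark.parametrize("name", FIXTURE_NAMES)
    def test_fixture_callables_match_coefficient_maps(self, name, rng):
        model = make_fixture(name)
        for _ in range(20):
            x = tuple(rng.uniform(-2, 2, model.n_components))
            t = rng.uniform(0, 10)
            for l in range(model.n_components):
                from sparsedyn.terms import parse_term

                expect = sum(
                    c
                    * float(
                        parse_term(k, model.names, omega=model.params.get("omega")).evaluate(
                            {**{n: np.array([v]) for n, v in zip(model.names, x)},
                             "t": np.array([t])}
                        )[0]
                    )
                    for k, c in model.drift_coeffs[l].items()
                )
                assert model.drift[l](x, t) == pytest.approx(expect, rel=1e-12)

    def test_three_well_drift_is_negative_potential_gradient(self, rng):
        xs = sympy.symbols("x")
        U = xs**6 - 6 * xs**4 + 0.5 * xs**3 + 8 * xs**2
        dU = sympy.lambdify(xs, -sympy.diff(U, xs))
        model = make_fixture("three_well")
        for x in rng.uniform(-3, 3, 100):
            assert model.drift[0]((x,), 0.0) == pytest.approx(dU(x), rel=1e-10)

    def test_three_well_drift_vanishes_at_origin(self):
        assert make_fixture("three_well").drift[0]((0.0,), 0.0) == 0.0

    def test_time_dependent_drift_at_t_zero(self):
        model = make_fixture("time_dependent")
        a0 = model.params["a0"]
        x = 1.3
        assert model.drift[0]((x,), 0.0) == pytest.approx(a0 * x - x**3)

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            make_fixture("pentuple_well")


class TestEulerMaruyama:
    def test_zero_diffusion_limit_is_forward_euler(self):
        model = SDEModel.from_coefficients(("x",), ({"x": -1.0},), ({"1": 1e-30},))
        traj = euler_maruyama(model, 1.0, 0.01, 100, seed=0)
        expect = 1.0 * (1 - 0.01) ** np.arange(101)
        assert traj.values[:, 0] == pytest.approx(expect, rel=1e-6)

    def test_free_diffusion_variance_law(self):
        # D1 = 0, D2 = c: Var X_N = 2 c N dt exactly for the discrete scheme
        c, n, dt, reps = 0.5, 50, 0.01, 2000
        model = SDEModel.from_coefficients(("x",), ({},), ({"1": c},))
        finals = np.array(
            [euler_maruyama(model, 0.0, dt, n, seed=s).values[-1, 0] for s in range(reps)]
        )
        var = 2 * c * n * dt
        se = var * np.sqrt(2.0 / reps)
        assert abs(finals.var() - var) < 3 * se

    def test_double_well_occupies_two_clusters(self):
        model = make_fixture("double_well")
        traj = euler_maruyama(model, 0.5, 5e-3, 1_000_000, seed=8)
        x = traj.values[:, 0]
        left = ((x > 0.0) & (x < 1.5)).mean()
        right = ((x > 2.5) & (x < 4.5)).mean()
        barrier = ((x > 1.7) & (x < 2.1)).mean()
        # the left well is ~3.7 energy units deeper, so with D2 = 0.8 the
        # metastable right cluster carries only a few percent of the weight
        assert left > 0.5 and right > 0.005
        assert barrier < right  # clusters are separated by a depleted region

    def test_seed_reproducible(self):
        model = make_fixture("double_well")
        a = euler_maruyama(model, 0.5, 5e-3, 1000, seed=3)
        b = euler_maruyama(model, 0.5, 5e-3, 1000, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_zero_control_equals_uncontrolled(self):
        model = make_fixture("double_well")
        a = euler_maruyama(model, 0.5, 5e-3, 1000, seed=3)
        b = euler_maruyama(model, 0.5, 5e-3, 1000, seed=3, control=[lambda x, t: 0.0])
        assert np.array_equal(a.values, b.values)
        assert np.all(b.control == 0)

    def test_blowup_reports_last_valid_index(self):
        model = SDEModel.from_coefficients(("x",), ({"x^3": 10.0},), ({"1": 0.1},))
        with pytest.raises(SimulationBlowup) as exc:
            euler_maruyama(model, 2.0, 0.1, 1000, seed=0)
        assert exc.value.last_valid < 1000

    def test_nonpositive_diffusion_rejected(self):
        model = SDEModel.from_coefficients(("x",), ({},), ({"1": -1.0},))
        with pytest.raises(SimulationBlowup, match="diffusion"):
            euler_maruyama(model, 0.0, 0.01, 10, seed=0)


class TestLorenz:
    def test_origin_is_equilibrium(self):
        traj = integrate_lorenz(LorenzParams(x0=(0.0, 0.0, 0.0), t_end=0.1))
        assert np.max(np.abs(traj.values)) == 0.0

    def test_volume_contraction_matches_jacobian_trace(self):
        # flow divergence is −(a + 1 + c) everywhere; measure it numerically
        # from the volume of a small perturbation simplex over a short time
        p = LorenzParams(dt=1e-4, t_end=0.05)
        eps = 1e-6
        base = integrate_lorenz(p).values[-1]
        cols = []
        for i in range(3):
            x0 = np.array(p.x0)
            x0[i] += eps
            pert = integrate_lorenz(
                LorenzParams(dt=p.dt, t_end=p.t_end, x0=tuple(x0))
            ).values[-1]
            cols.append((pert - base) / eps)
        vol = abs(np.linalg.det(np.array(cols).T))
        rate = np.log(vol) / p.t_end
        assert rate == pytest.approx(-(p.a + 1 + p.c), rel=1e-3)

    def test_default_run_stays_bounded(self):
        traj = integrate_lorenz()
        assert traj.n_samples == 125_001
        assert np.max(np.abs(traj.values)) < 100


class TestLambdaOmega:
    @staticmethod
    def _solve_with_ic(p, u0, v0, **kw):
        import sparsedyn.fixtures as fx

        orig = fx._spiral_ic
        fx._spiral_ic = lambda pp: (np.full((pp.n, pp.n), u0), np.full((pp.n, pp.n), v0))
        try:
            return solve_lambda_omega(p, burn_in=0.0, **kw)
        finally:
            fx._spiral_ic = orig

    def test_zero_field_is_fixed_point(self):
        fs = self._solve_with_ic(RDParams(n=32, t_end=0.05), 0.0, 0.0)
        assert np.max(np.abs(fs.fields["u"])) == 0.0
        assert np.max(np.abs(fs.fields["v"])) == 0.0

    def test_uniform_state_matches_ode_reduction(self):
        # spatially uniform fields remove diffusion: compare against an
        # independent ODE integration of the reaction terms
        from scipy.integrate import solve_ivp

        p = RDParams(n=32, t_end=0.4, dt=0.002)
        u0, v0 = 0.4, -0.2
        series = self._solve_with_ic(p, u0, v0)

        def rhs(t, y):
            u, v = y
            A2 = (u * u + v * v) ** 2
            return [u - A2 * u + p.beta_rd * A2 * v, v - A2 * v - p.beta_rd * A2 * u]

        sol = solve_ivp(rhs, (0, p.t_end), [u0, v0], rtol=1e-10, atol=1e-12,
                        t_eval=series.times)
        assert np.max(np.abs(series.fields["u"][:, 0, 0] - sol.y[0])) < 1e-6
        assert np.max(np.abs(series.fields["v"][:, 0, 0] - sol.y[1])) < 1e-6

    def test_default_run_completes_with_bounded_fields(self):
        fs = solve_lambda_omega(RDParams(n=64, t_end=0.1), burn_in=0.0)
        assert fs.n_snapshots == int(round(0.1 / 0.0034)) + 1
        assert np.max(np.abs(fs.fields["u"])) < 2.0


class TestNoise:
    def test_zero_fraction_is_identity(self, rng):
        data = rng.standard_normal((100, 2))
        assert np.array_equal(add_noise(data, 0.0, 1), data)

    def test_constant_coordinate_unchanged(self, rng):
        data = np.column_stack([np.full(200, 3.0), rng.standard_normal(200)])
        noisy = add_noise(data, 0.05, 2)
        assert np.array_equal(noisy[:, 0], data[:, 0])
        assert not np.array_equal(noisy[:, 1], data[:, 1])

    def test_noise_level_matches_fraction(self, rng):
        data = rng.standard_normal((200_000, 1))
        noisy = add_noise(data, 0.1, 3)
        ratio = (noisy - data).std() / data.std()
        assert ratio == pytest.approx(0.1, rel=0.02)

    def test_denoise_none_is_identity(self, rng):
        from sparsedyn.library import FieldSeries

        fs = FieldSeries(fields={"u": rng.standard_normal((6, 16, 16))}, dx=0.1, dt=0.1)
        out = denoise(fs, "none")
        assert np.array_equal(out.fields["u"], fs.fields["u"])

    @pytest.mark.parametrize("method", ["spectral_lowpass", "gaussian_smooth", "wavelet_shrink"])
    def test_denoising_reduces_pure_noise_variance(self, method, rng):
        from sparsedyn.library import FieldSeries

        fs = FieldSeries(fields={"u": rng.standard_normal((4, 32, 32))}, dx=0.1, dt=0.1)
        out = denoise(fs, method)
        assert out.fields["u"].var() < fs.fields["u"].var()
        assert out.meta["denoise"]["method"] == method

    def test_unknown_method_rejected(self, rng):
        from sparsedyn.library import FieldSeries

        fs = FieldSeries(fields={"u": rng.standard_normal((4, 8, 8))}, dx=0.1, dt=0.1)
        with pytest.raises(ValueError, match="unknown denoising"):
            denoise(fs, "curvelet")
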