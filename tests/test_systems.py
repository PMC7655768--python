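"""Simulators: fixed points, conservation laws, analytic derivatives, noise."""

import numpy as np
import pytest

from sindypi import systems
from sindypi.pde import FieldData


class TestMichaelisMenten:
    def test_fixed_point_is_stationary(self):
        # j_x (K_m + x) = V_max x at x = 0.2 for the default parameters
        t = np.arange(0.0, 10.0, 0.01)
        data = systems.simulate_michaelis_menten(x0=0.2, t=t)
        assert np.max(np.abs(data.X - 0.2)) < 1e-6

    def test_monotone_decay_toward_fixed_point(self):
        t = np.arange(0.0, 10.0, 0.01)
        data = systems.simulate_michaelis_menten(x0=0.5, t=t)
        x = data.X[:, 0]
        assert np.all(np.diff(x) <= 1e-12)
        assert abs(x[-1] - 0.2) < 1e-3

    def test_zero_vmax_gives_linear_influx(self):
        t = np.arange(0.0, 2.0, 0.01)
        data = systems.simulate_michaelis_menten(
            systems.MMParams(V_max=0.0), x0=0.1, t=t)
        assert np.allclose(data.X[:, 0], 0.1 + 0.6 * t, atol=1e-8)

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(ValueError):
            systems.simulate_michaelis_menten(x0=-0.1)


class TestGlycolysis:
    def test_x5_rate_vanishes_when_sources_zero(self):
        p = systems.GlycolysisParams()
        x = np.array([0.0, 1.0, 0.5, 0.2, 0.0, 0.3, 0.1])
        rhs = systems.glycolysis_rhs(x, p)
        assert rhs[4] == 0.0          # g1*x1 + g2*x5 with x1 = x5 = 0

    def test_zero_state_rate_is_influx_constant(self):
        p = systems.GlycolysisParams()
        rhs = systems.glycolysis_rhs(np.zeros(7), p)
        assert rhs[0] == p.c1
        assert np.allclose(rhs[1:], 0.0)

    def test_rhs_matches_independent_symbolic_evaluation(self):
        import sympy as sp
        p = systems.GlycolysisParams()
        xs = sp.symbols("x1:8")
        x1, x2, x3, x4, x5, x6, x7 = xs
        exprs = [
            p.c1 + p.c2 * x1 * x6 / (1 + p.c3 * x6**4),
            p.d1 * x1 * x6 / (1 + p.d2 * x6**4) + p.d3 * x2
            + p.d4 * x2 * x7,
            p.e1 * x2 + p.e2 * x3 + p.e3 * x2 * x7 + p.e4 * x3 * x6
            + p.f5 * x4 * x7,
            p.f1 * x3 + p.f2 * x4 + p.f3 * x5 + p.f4 * x3 * x6
            + p.f5 * x4 * x7,
            p.g1 * x1 + p.g2 * x5,
            (p.h3 * x3 + p.h5 * x6 + p.h4 * x3 * x6 + p.h1 * x1 * x6)
            / (1 + p.h2 * x6**4),
            p.j1 * x2 + p.j2 * x2 * x7 + p.j3 * x4 * x7,
        ]
        fns = [sp.lambdify(xs, e, "numpy") for e in exprs]
        rng = np.random.default_rng(0)
        for _ in range(50):
            state = rng.uniform(0.01, 2.0, 7)
            got = systems.glycolysis_rhs(state, p)
            want = np.array([f(*state) for f in fns])
            assert np.allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_trajectory_attaches_analytic_derivatives(self):
        # centered differences of the trajectory converge to the attached
        # analytic derivatives at the expected O(dt^2) rate
        errs = {}
        for dt in (0.005, 0.001):
            data = systems.simulate_yeast_glycolysis(
                t=np.arange(0.0, 0.5, dt))
            num = np.gradient(data.X, dt, axis=0, edge_order=2)
            scale = np.linalg.norm(data.Xdot, axis=0)
            errs[dt] = np.linalg.norm(num[3:-3] - data.Xdot[3:-3],
                                      axis=0) / scale
        assert np.all(errs[0.001] < 1e-3)
        assert np.all(errs[0.001] < errs[0.005] / 10)


class TestCartPendulum:
    def test_rest_state_without_force_is_stationary(self):
        p = systems.CartPoleParams()
        rhs = systems.cart_pendulum_rhs(np.zeros(4), 0.0, p)
        assert np.allclose(rhs, 0.0)

    def test_cart_acceleration_at_hanging_angle(self):
        # at phi = 0 the cart equation reduces to F L1 / (L1 (M+m-m)) = F/M
        p = systems.CartPoleParams()
        rhs = systems.cart_pendulum_rhs(np.zeros(4), 2.0, p)
        assert np.isclose(rhs[3], 2.0 / p.M)
        # the pendulum equation couples through -F cos(phi) / (L1 M)
        assert np.isclose(rhs[2], -2.0 / (p.L1 * p.M))

    @staticmethod
    def _energy(p, X):
        phi, _, phidot, sdot = X.T
        T = 0.5 * (p.M + p.m) * sdot**2 \
            + p.m * p.L1 * sdot * phidot * np.cos(phi) \
            + 0.5 * p.m * p.L1**2 * phidot**2
        V = -p.m * p.g * p.L1 * np.cos(phi)
        return T + V

    def test_unforced_energy_conserved(self):
        p = systems.CartPoleParams()
        t = np.arange(0.0, 10.0, 0.001)
        data = systems.simulate_cart_pendulum(
            p, x0=(0.4, 0.0, 0.2, 0.1), forcing=lambda tt: 0.0 * tt, t=t)
        E = self._energy(p, data.X)
        assert np.max(np.abs(E - E[0])) / abs(E[0]) < 1e-6

    def test_forced_work_energy_balance(self):
        p = systems.CartPoleParams()
        t = np.arange(0.0, 10.0, 0.001)
        forcing = lambda tt: -0.2 + 0.5 * np.sin(6 * tt)  # noqa: E731
        data = systems.simulate_cart_pendulum(p, t=t, forcing=forcing)
        E = self._energy(p, data.X)
        sdot = data.X[:, 3]
        work = np.concatenate([[0.0], np.cumsum(
            forcing(t[:-1]) * sdot[:-1] * np.diff(t))])
        scale = np.max(np.abs(E - E[0])) + 1.0
        assert np.max(np.abs(E - E[0] - work)) / scale < 5e-3

    def test_truth_terms_contained_in_default_library(self):
        from sindypi.library import enumerate_terms
        for eq in ("phidot", "sdot"):
            labels = {t.label for t in enumerate_terms(
                systems.cart_pendulum_library_spec(eq))}
            assert systems.cart_pendulum_truth(eq) <= labels


class TestDoublePendulum:
    @pytest.fixture(scope="class")
    def short_run(self):
        t = np.arange(0.0, 10.0, 0.001)
        return systems.simulate_double_pendulum(t=t, friction=False)

    def test_frictionless_energy_conserved(self, short_run):
        p = systems.DoublePendulumParams()
        E = systems.double_pendulum_energy(short_run.X, p)
        scale = max(abs(E[0]), 1.0)
        assert np.max(np.abs(E - E[0])) / scale < 1e-6

    def test_friction_dissipates_energy(self):
        p = systems.DoublePendulumParams(k1=0.05, k2=0.02)
        t = np.arange(0.0, 5.0, 0.001)
        data = systems.simulate_double_pendulum(p, t=t, friction=True)
        E = systems.double_pendulum_energy(data.X, p)
        drops = np.diff(E)
        assert E[-1] < E[0]
        assert np.all(drops < 1e-8)

    def test_stable_equilibrium_is_stationary(self):
        t = np.arange(0.0, 2.0, 0.001)
        data = systems.simulate_double_pendulum(
            x0=(0.0, 0.0, 0.0, 0.0), t=t, friction=False)
        assert np.max(np.abs(data.X)) < 1e-10


class TestKdV:
    def test_pure_kdv_conserves_mass(self):
        p = systems.KdVParams(gamma=0.0, g0=0.0, T=0.5)
        field = systems.simulate_modified_kdv(p)
        mass = field.fields["u"].sum(axis=1) * field.dx
        assert np.max(np.abs(mass - mass[0])) / abs(mass[0]) < 1e-6

    def test_zero_field_is_fixed_point_without_gain(self):
        p = systems.KdVParams(gamma=0.1, g0=0.0, T=0.2)
        field = systems.simulate_modified_kdv(p, u0=np.zeros(128))
        assert np.max(np.abs(field.fields["u"])) < 1e-10

    def test_grid_constraints(self):
        with pytest.raises(ValueError):
            systems.KdVParams(n=100)


class TestBZ:
    def test_uniform_fields_reduce_to_reaction_ode(self):
        from scipy.integrate import solve_ivp
        p = systems.BZParams(Dx=0.0, Dz=0.0, Ds=0.0, Du=1.0, T=0.5)
        # zero diffusion for x,z,s; u diffuses but is uniform so lap = 0
        init = tuple(np.full(p.n, v) for v in (0.4, 0.3, 0.2, 0.1))
        field = systems.simulate_bz(p, init=init)

        def ode(_t, y):
            return systems.bz_reaction_rhs(*y, p)
        sol = solve_ivp(ode, (0.0, p.T), [0.4, 0.3, 0.2, 0.1],
                        t_eval=field.t, rtol=1e-10, atol=1e-12)
        for i, nm in enumerate(("bx", "bz", "bs", "bu")):
            diff = np.abs(field.fields[nm] - sol.y[i][:, None])
            assert diff.max() < 1e-6

    def test_reaction_rhs_matches_symbolic(self):
        import sympy as sp
        p = systems.BZParams()
        x, z, s, u = sp.symbols("x z s u", positive=True)
        exprs = [
            (p.f * z * (p.q - x) / (p.q + x) + x - x**2 - p.beta * x + s)
            / p.eps,
            x - z - p.alpha * z + p.gamma * u,
            (p.beta * x - s + p.chi * u) / p.eps2,
            (p.alpha * z - (p.gamma + p.chi2) * u) / p.eps3,
        ]
        fns = [sp.lambdify((x, z, s, u), e, "numpy") for e in exprs]
        rng = np.random.default_rng(1)
        for _ in range(20):
            st = rng.uniform(0.05, 1.0, 4)
            got = systems.bz_reaction_rhs(*st, p)
            want = [f(*st) for f in fns]
            assert np.allclose(got, want, rtol=1e-12)

    def test_spectral_laplacian_of_gaussian(self):
        p = systems.BZParams()
        n = p.n
        L = p.x_max - p.x_min
        x = p.x_min + L * np.arange(n) / n
        g = np.exp(-x**2)
        k = 2 * np.pi * np.fft.fftfreq(n, d=L / n)
        lap = np.real(np.fft.ifft(-(k**2) * np.fft.fft(g)))
        analytic = (4 * x**2 - 2) * np.exp(-x**2)
        assert np.max(np.abs(lap - analytic)) < 1e-6


class TestAddNoise:
    def test_zero_sigma_is_identity(self, mm_data):
        noisy = systems.add_noise(mm_data, 0.0, seed=1)
        assert np.array_equal(noisy.X, mm_data.X)
        assert np.array_equal(noisy.Xdot, mm_data.Xdot)

    def test_seed_reproducibility(self, mm_data):
        a = systems.add_noise(mm_data, 0.05, seed=9)
        b = systems.add_noise(mm_data, 0.05, seed=9)
        assert np.array_equal(a.X, b.X)

    def test_noise_statistics(self):
        t = np.arange(100_000, dtype=float)
        from sindypi.library import TimeSeriesData
        clean = TimeSeriesData(t=t, X=np.zeros((t.size, 2)),
                               state_names=("a", "b"))
        noisy = systems.add_noise(clean, 0.3, seed=0)
        sd = noisy.X.std(axis=0)
        assert np.all(np.abs(sd - 0.3) / 0.3 < 0.02)
        r = np.corrcoef(noisy.X[:, 0], noisy.X[:, 1])[0, 1]
        assert abs(r) < 0.02

    def test_negative_sigma_rejected(self, mm_data):
        with pytest.raises(ValueError):
            systems.add_noise(mm_data, -0.1, seed=0)

    def test_derivatives_left_untouched(self, mm_data):
        noisy = systems.add_noise(mm_data, 0.1, seed=2)
        assert np.array_equal(noisy.Xdot, mm_data.Xdot)

    def test_field_noise(self):
        field = FieldData(fields={"u": np.zeros((10, 8))},
                          x=np.arange(8.0), t=np.arange(10.0))
        noisy = systems.add_noise(field, 0.1, seed=3)
        assert noisy.fields["u"].shape == (10, 8)
        assert noisy.fields["u"].std() > 0
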