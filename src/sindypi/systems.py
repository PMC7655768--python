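"""Synthetic-data generators: simulators for the benchmark systems.

Every simulator integrates its governing equations with a tight-tolerance
adaptive Runge-Kutta scheme and attaches *analytic* derivatives (the
right-hand side evaluated along the solution), so differentiation noise is
opt-in rather than baked into the data.  Gaussian measurement noise is
injected separately and reproducibly by :func:`add_noise`.

Systems: Michaelis-Menten enzyme kinetics, the seven-state yeast glycolysis
network, a forced single pendulum on a cart, a mounted compound double
pendulum (equations derived symbolically from the Euler-Lagrange
formalism), a modified Korteweg-de Vries equation with a rational gain
term, and a simplified Belousov-Zhabotinsky reaction-diffusion model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .library import LibrarySpec, TimeSeriesData
from .pde import FieldData

__all__ = [
    "MMParams", "GlycolysisParams", "CartPoleParams", "DoublePendulumParams",
    "KdVParams", "BZParams",
    "simulate_michaelis_menten", "simulate_yeast_glycolysis",
    "simulate_cart_pendulum", "simulate_double_pendulum",
    "simulate_modified_kdv", "simulate_bz", "add_noise",
    "mm_library_spec", "mm_truth_support",
    "glycolysis_x6_library_spec", "glycolysis_x6_truth",
    "cart_pendulum_library_spec", "cart_pendulum_truth",
]

_IVP_OPTS = dict(rtol=1e-10, atol=1e-12, method="RK45")


def _integrate(rhs, x0, t, **kw):
    opts = dict(_IVP_OPTS)
    opts.update(kw)
    sol = solve_ivp(rhs, (t[0], t[-1]), np.asarray(x0, float), t_eval=t,
                    **opts)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.y.T


# ---------------------------------------------------------------------------
# Michaelis-Menten enzyme kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MMParams:
    """Substrate influx j_x, maximum uptake rate V_max, half-max constant K_m."""

    j_x: float = 0.6
    V_max: float = 1.5
    K_m: float = 0.3

    def __post_init__(self) -> None:
        if self.K_m <= 0 or self.V_max < 0:
            raise ValueError("K_m must be positive, V_max non-negative")


def simulate_michaelis_menten(params: MMParams = MMParams(), x0: float = 0.5,
                              t: np.ndarray | None = None) -> TimeSeriesData:
    """Single-substrate saturating kinetics xdot = j_x - V_max x/(K_m + x)."""
    if t is None:
        t = np.arange(0.0, 10.0 + 1e-12, 0.001)
    if x0 < 0:
        raise ValueError("concentration must be non-negative")

    def rhs(_t, x):
        return params.j_x - params.V_max * x / (params.K_m + x)

    X = _integrate(rhs, [x0], t)
    Xdot = rhs(None, X[:, 0])[:, None]
    return TimeSeriesData(t=t, X=X, Xdot=Xdot, state_names=("x",))


def mm_library_spec(degree: int = 2) -> LibrarySpec:
    """Implicit library for the kinetics problem: {1, x, .., x^d} x {1, dx}."""
    return LibrarySpec(state_names=("x",), degree=degree)


def mm_truth_support(params: MMParams = MMParams()) -> frozenset[str]:
    """Support of the cleared-denominator relation.

    xdot (K_m + x) = j_x (K_m + x) - V_max x  =>  {dx, dx*x, 1, x}; the x
    coefficient j_x - V_max vanishes only for j_x == V_max.
    """
    support = {"dx", "dx*x", "1"}
    if params.j_x != params.V_max:
        support.add("x")
    return frozenset(support)


# ---------------------------------------------------------------------------
# yeast glycolysis (seven states)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlycolysisParams:
    """Coefficient sets of the seven rate equations.

    Defaults follow the allosteric-ATP glycolysis lineage the model derives
    from (mapped onto the structural form above); they are configuration,
    not fitted values.  The x6 equation uses a shared Hill-type denominator
    1 + h2 x6^4 across its numerator terms.
    """

    c1: float = 2.5
    c2: float = -100.0
    c3: float = 13.6769
    d1: float = 200.0
    d2: float = 13.6769
    d3: float = -6.0
    d4: float = -6.0
    e1: float = 6.0
    e2: float = -64.0
    e3: float = -6.0
    e4: float = 16.0
    f1: float = 64.0
    f2: float = -13.0
    f3: float = 13.0
    f4: float = -16.0
    f5: float = -100.0
    g1: float = 1.3
    g2: float = -3.1
    h1: float = -100.0
    h2: float = 13.6769
    h3: float = 12.8
    h4: float = -3.2
    h5: float = -1.28
    j1: float = 1.8
    j2: float = -1.8
    j3: float = -1.0


def glycolysis_rhs(x: np.ndarray, p: GlycolysisParams) -> np.ndarray:
    """Right-hand side of the seven-state network (vectorized over rows)."""
    x = np.asarray(x, dtype=float)
    x1, x2, x3, x4, x5, x6, x7 = (x[..., i] for i in range(7))
    hill = 1.0 + p.c3 * x6**4
    hill_d = 1.0 + p.d2 * x6**4
    hill_h = 1.0 + p.h2 * x6**4
    return np.stack([
        p.c1 + p.c2 * x1 * x6 / hill,
        p.d1 * x1 * x6 / hill_d + p.d3 * x2 + p.d4 * x2 * x7,
        p.e1 * x2 + p.e2 * x3 + p.e3 * x2 * x7 + p.e4 * x3 * x6
        + p.f5 * x4 * x7,
        p.f1 * x3 + p.f2 * x4 + p.f3 * x5 + p.f4 * x3 * x6 + p.f5 * x4 * x7,
        p.g1 * x1 + p.g2 * x5,
        (p.h3 * x3 + p.h5 * x6 + p.h4 * x3 * x6 + p.h1 * x1 * x6) / hill_h,
        p.j1 * x2 + p.j2 * x2 * x7 + p.j3 * x4 * x7,
    ], axis=-1)


def simulate_yeast_glycolysis(params: GlycolysisParams = GlycolysisParams(),
                              x0=None,
                              t: np.ndarray | None = None) -> TimeSeriesData:
    """Integrate the seven-state metabolic network with analytic derivatives."""
    if x0 is None:
        x0 = np.array([1.0, 1.0, 0.1, 0.2, 0.15, 1.0, 0.07])
    if t is None:
        t = np.arange(0.0, 5.0 + 1e-12, 0.005)
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("states are concentrations; x0 must be non-negative")

    X = _integrate(lambda _t, x: glycolysis_rhs(x, params), x0, t)
    return TimeSeriesData(t=t, X=X, Xdot=glycolysis_rhs(X, params))


def glycolysis_x6_library_spec() -> LibrarySpec:
    """Library for discovering the x6 equation: polynomials in (x1, x3, x6)
    to degree 2 plus the Hill monomial x6^4, crossed with {1, dx6}."""
    return LibrarySpec(
        state_names=("x1", "x3", "x6"), derivative_names=("dx6",), degree=2,
        extra_monomials=((("x6", 4),),))


def glycolysis_x6_truth() -> frozenset[str]:
    """Cleared-denominator support of the x6 equation:
    dx6 (1 + h2 x6^4) = h3 x3 + h5 x6 + h4 x3 x6 + h1 x1 x6."""
    return frozenset({"dx6", "dx6*x6^4", "x3", "x6", "x3*x6", "x1*x6"})


# ---------------------------------------------------------------------------
# single pendulum on a cart, with control input
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CartPoleParams:
    """Cart mass M, pendulum mass m, arm length L1, gravity g.

    Unit mechanical parameters with physical gravity by default.
    """

    M: float = 1.0
    m: float = 1.0
    L1: float = 1.0
    g: float = 9.81

    def __post_init__(self) -> None:
        if min(self.M, self.m, self.L1, self.g) <= 0:
            raise ValueError("all parameters must be positive")


def cart_pendulum_rhs(x: np.ndarray, F: np.ndarray,
                      p: CartPoleParams) -> np.ndarray:
    """Equations of motion for states [phi, s, phidot, sdot] under force F.

    Angle measured from the hanging position; the mass-matrix denominator
    is M + m - m cos^2(phi).  Signs are the Euler-Lagrange-consistent ones
    (the unforced system conserves energy and forcing enters through the
    work-energy balance dE/dt = F sdot).
    """
    x = np.asarray(x, dtype=float)
    phi, phidot = x[..., 0], x[..., 2]
    F = np.asarray(F, dtype=float)
    s_, c_ = np.sin(phi), np.cos(phi)
    den = p.M + p.m - p.m * c_**2
    phiddot = -((p.M + p.m) * p.g * s_ + F * p.L1 * c_
                + p.m * p.L1**2 * s_ * c_ * phidot**2) / (p.L1**2 * den)
    sddot = (p.m * p.L1**2 * s_ * phidot**2 + F * p.L1
             + p.m * p.g * s_ * c_) / (p.L1 * den)
    return np.stack([phidot, x[..., 3], phiddot, sddot], axis=-1)


def simulate_cart_pendulum(params: CartPoleParams = CartPoleParams(),
                           x0=(0.3, 0.0, 1.0, 0.0), forcing=None,
                           t: np.ndarray | None = None) -> TimeSeriesData:
    """Forced cart-pendulum trajectory with the force recorded as a control."""
    if t is None:
        t = np.arange(0.0, 16.0 + 1e-12, 0.001)
    if forcing is None:
        forcing = lambda tt: -0.2 + 0.5 * np.sin(6 * tt)  # noqa: E731

    def rhs(tt, x):
        return cart_pendulum_rhs(x, forcing(tt), params)

    X = _integrate(rhs, x0, t)
    F = np.asarray(forcing(t), dtype=float) * np.ones_like(t)
    return TimeSeriesData(
        t=t, X=X, Xdot=cart_pendulum_rhs(X, F, params), U=F[:, None],
        state_names=("phi", "s", "phidot", "sdot"), control_names=("F",))


def cart_pendulum_library_spec(equation: str = "phidot") -> LibrarySpec:
    """Trig + polynomial library for one acceleration equation.

    Polynomials in phidot (degree 2) and the force F (degree 1), trig
    products of phi up to degree 2, crossed with the equation's own
    acceleration {1, dphidot} or {1, dsdot}.
    """
    if equation not in ("phidot", "sdot"):
        raise ValueError("equation must be 'phidot' or 'sdot'")
    return LibrarySpec(
        state_names=("phi", "s", "phidot", "sdot"),
        derivative_names=("d" + equation,),
        control_names=("F",), degree=2, trig_states=("phi",), trig_degree=2,
        max_exponent=(("F", 1), ("phi", 0), ("s", 0), ("sdot", 0)))


def cart_pendulum_truth(equation: str = "phidot") -> frozenset[str]:
    """Cleared-denominator support of Eq of motion for the chosen state."""
    if equation == "phidot":
        return frozenset({"dphidot", "dphidot*cos(phi)^2", "sin(phi)",
                          "F*cos(phi)", "phidot^2*cos(phi)*sin(phi)"})
    return frozenset({"dsdot", "dsdot*cos(phi)^2", "phidot^2*sin(phi)",
                      "F", "cos(phi)*sin(phi)"})


# ---------------------------------------------------------------------------
# mounted double pendulum (symbolic Euler-Lagrange derivation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoublePendulumParams:
    """Compound double pendulum: masses, lengths, COM offsets, inertias.

    Joint friction constants k1 (base) and k2 (elbow) act as viscous
    torques; the defaults are the hardware values of the physical apparatus
    this system models.
    """

    m1: float = 1.0
    m2: float = 1.0
    L1: float = 1.0
    L2: float = 1.0
    a1: float = 0.5
    a2: float = 0.5
    I1: float = 1.0 / 12.0
    I2: float = 1.0 / 12.0
    g: float = 9.81
    k1: float = 7.2484e-4
    k2: float = 1.6522e-4


_DP_CACHE: dict[tuple, object] = {}


def _double_pendulum_accel(p: DoublePendulumParams):
    """Symbolically derived angular accelerations (cached lambdified fns)."""
    key = (p.m1, p.m2, p.L1, p.L2, p.a1, p.a2, p.I1, p.I2, p.g)
    if key in _DP_CACHE:
        return _DP_CACHE[key]
    import sympy as sp

    t = sp.symbols("t")
    ph1, ph2 = sp.Function("ph1")(t), sp.Function("ph2")(t)
    q = [ph1, ph2]
    qd = [sp.diff(v, t) for v in q]
    m1, m2, L1, a1, a2, I1, I2, g = sp.symbols(
        "m1 m2 L1 a1 a2 I1 I2 g", positive=True)
    tau1, tau2 = sp.symbols("tau1 tau2")  # generalized friction torques

    # COM velocities (angles measured from the downward vertical)
    v1sq = (a1 * qd[0]) ** 2
    v2x = L1 * qd[0] * sp.cos(ph1) + a2 * qd[1] * sp.cos(ph2)
    v2y = L1 * qd[0] * sp.sin(ph1) + a2 * qd[1] * sp.sin(ph2)
    T = (m1 * v1sq + I1 * qd[0] ** 2 + m2 * (v2x**2 + v2y**2)
         + I2 * qd[1] ** 2) / 2
    V = -(m1 * a1 + m2 * L1) * g * sp.cos(ph1) - m2 * a2 * g * sp.cos(ph2)
    L = T - V
    taus = [tau1, tau2]
    eqs = [sp.diff(sp.diff(L, qd[i]), t) - sp.diff(L, q[i]) - taus[i]
           for i in range(2)]
    qdd = [sp.diff(v, t) for v in qd]
    sol = sp.solve(eqs, qdd, dict=True)[0]
    subs = {m1: p.m1, m2: p.m2, L1: p.L1, a1: p.a1, a2: p.a2,
            I1: p.I1, I2: p.I2, g: p.g}
    s_ph1, s_ph2, s_w1, s_w2 = sp.symbols("s_ph1 s_ph2 s_w1 s_w2")
    repl = {ph1: s_ph1, ph2: s_ph2, qd[0]: s_w1, qd[1]: s_w2}
    fns = tuple(
        sp.lambdify((s_ph1, s_ph2, s_w1, s_w2, tau1, tau2),
                    sol[qdd[i]].subs(subs).subs(repl), "numpy")
        for i in range(2))
    _DP_CACHE[key] = fns
    return fns


def double_pendulum_rhs(x: np.ndarray, p: DoublePendulumParams,
                        friction: bool = True) -> np.ndarray:
    acc1, acc2 = _double_pendulum_accel(p)
    x = np.asarray(x, dtype=float)
    ph1, ph2, w1, w2 = (x[..., i] for i in range(4))
    if friction:
        tau1 = -p.k1 * w1 + p.k2 * (w2 - w1)
        tau2 = -p.k2 * (w2 - w1)
    else:
        tau1 = tau2 = np.zeros_like(w1)
    return np.stack([w1, w2,
                     acc1(ph1, ph2, w1, w2, tau1, tau2),
                     acc2(ph1, ph2, w1, w2, tau1, tau2)], axis=-1)


def double_pendulum_energy(x: np.ndarray, p: DoublePendulumParams) -> np.ndarray:
    """Total mechanical energy (for conservation checks)."""
    x = np.asarray(x, dtype=float)
    ph1, ph2, w1, w2 = (x[..., i] for i in range(4))
    v2x = p.L1 * w1 * np.cos(ph1) + p.a2 * w2 * np.cos(ph2)
    v2y = p.L1 * w1 * np.sin(ph1) + p.a2 * w2 * np.sin(ph2)
    T = 0.5 * (p.m1 * (p.a1 * w1) ** 2 + p.I1 * w1**2
               + p.m2 * (v2x**2 + v2y**2) + p.I2 * w2**2)
    V = -(p.m1 * p.a1 + p.m2 * p.L1) * p.g * np.cos(ph1) \
        - p.m2 * p.a2 * p.g * np.cos(ph2)
    return T + V


def simulate_double_pendulum(params: DoublePendulumParams = DoublePendulumParams(),
                             x0=(np.pi + 1.2, np.pi - 0.6, 0.0, 0.0),
                             t: np.ndarray | None = None,
                             friction: bool = True) -> TimeSeriesData:
    """Chaotic compound double pendulum with optional viscous joint friction."""
    if t is None:
        t = np.arange(0.0, 10.0 + 1e-12, 0.001)
    X = _integrate(lambda _t, x: double_pendulum_rhs(x, params, friction),
                   x0, t)
    return TimeSeriesData(
        t=t, X=X, Xdot=double_pendulum_rhs(X, params, friction),
        state_names=("phi1", "phi2", "phi1dot", "phi2dot"))


# ---------------------------------------------------------------------------
# modified KdV equation (spectral, periodic)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KdVParams:
    """u_t = -u_xxx - 6 u u_x - gamma u + 2 g0/(1+u) on a periodic domain."""

    gamma: float = 0.1
    g0: float = 1.0
    x_min: float = -10.0
    x_max: float = 10.0
    n: int = 128
    dt: float = 0.001
    T: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 64 or (self.n & (self.n - 1)) != 0:
            raise ValueError("n must be a power of two >= 64")


def kdv_rhs_fields(u: np.ndarray, ux: np.ndarray, uxxx: np.ndarray,
                   p: KdVParams) -> np.ndarray:
    if np.any(1.0 + u <= 0):
        raise RuntimeError("1 + u reached zero: rational gain term blows up")
    return -uxxx - 6.0 * u * ux - p.gamma * u + 2.0 * p.g0 / (1.0 + u)


def simulate_modified_kdv(params: KdVParams = KdVParams(), u0=None,
                          store_every: int = 10) -> FieldData:
    """Integrating-factor spectral solve; stores u and the analytic u_t."""
    p = params
    n = p.n
    Lx = p.x_max - p.x_min
    x = p.x_min + Lx * np.arange(n) / n
    if u0 is None:
        u0 = 0.8 * np.exp(-(x**2)) + 0.4 * np.exp(-((x - 4.0) ** 2) / 2.0)
    elif callable(u0):
        u0 = u0(x)
    u0 = np.asarray(u0, dtype=float)
    k = 2 * np.pi * np.fft.fftfreq(n, d=Lx / n)
    ik = 1j * k
    lin = 1j * k**3  # -u_xxx in Fourier space: -(ik)^3 = i k^3

    def nonlinear(u):
        ux = np.real(np.fft.ifft(ik * np.fft.fft(u)))
        return -6.0 * u * ux - p.gamma * u + 2.0 * p.g0 / (1.0 + u)

    def rhs(t, wr):
        w = wr[:n] + 1j * wr[n:]
        u = np.real(np.fft.ifft(np.exp(lin * t) * w))
        if np.min(1.0 + u) <= 1e-6:
            raise RuntimeError("1 + u reached zero during KdV integration")
        nw = np.exp(-lin * t) * np.fft.fft(nonlinear(u))
        return np.concatenate([nw.real, nw.imag])

    t_store = np.arange(0.0, p.T + 1e-12, p.dt * store_every)
    w0 = np.fft.fft(u0)
    sol = solve_ivp(rhs, (0.0, p.T), np.concatenate([w0.real, w0.imag]),
                    t_eval=t_store, rtol=1e-9, atol=1e-11, method="RK45")
    if not sol.success:
        raise RuntimeError(f"KdV integration failed: {sol.message}")
    U = np.empty((t_store.size, n))
    for i, tt in enumerate(sol.t):
        w = sol.y[:n, i] + 1j * sol.y[n:, i]
        U[i] = np.real(np.fft.ifft(np.exp(lin * tt) * w))
    spec = np.fft.fft(U, axis=1)
    Ux = np.real(np.fft.ifft(ik * spec, axis=1))
    Uxxx = np.real(np.fft.ifft(ik**3 * spec, axis=1))
    Ut = kdv_rhs_fields(U, Ux, Uxxx, p)
    return FieldData(fields={"u": U}, x=x, t=t_store, periodic=True,
                     field_t={"u_t": Ut})


# ---------------------------------------------------------------------------
# simplified Belousov-Zhabotinsky reaction (1-D reaction-diffusion)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BZParams:
    """Four-field oscillating reaction with diffusion ratios.

    Parameter defaults are documented configuration chosen for bounded,
    oscillatory dynamics; only the structural form matters for the
    identification demonstrations.
    """

    eps: float = 0.3
    eps2: float = 0.2
    eps3: float = 0.1
    f: float = 1.5
    q: float = 0.5
    alpha: float = 0.3
    beta: float = 0.26
    gamma: float = 0.4
    chi: float = 0.1
    chi2: float = 0.2
    Dx: float = 1.0
    Dz: float = 0.6
    Ds: float = 0.5
    Du: float = 1.0
    x_min: float = -10.0
    x_max: float = 10.0
    n: int = 128
    dt: float = 0.001
    T: float = 1.0

    def __post_init__(self) -> None:
        if min(self.eps, self.eps2, self.eps3) <= 0:
            raise ValueError("timescale parameters must be positive")


def bz_reaction_rhs(x, z, s, u, p: BZParams):
    """Reaction part of the four coupled fields (no diffusion)."""
    if np.any(p.q + x <= 0):
        raise RuntimeError("q + x reached zero: rational term blows up")
    rx = (p.f * z * (p.q - x) / (p.q + x) + x - x * x - p.beta * x + s) / p.eps
    rz = x - z - p.alpha * z + p.gamma * u
    rs = (p.beta * x - s + p.chi * u) / p.eps2
    ru = (p.alpha * z - (p.gamma + p.chi2) * u) / p.eps3
    return rx, rz, rs, ru


def simulate_bz(params: BZParams = BZParams(), init=None,
                store_every: int = 10, seed: int = 0) -> FieldData:
    """Spectral 1-D reaction-diffusion solve of the four-field model.

    The default initial condition is a seeded mixture of Gaussian bumps on
    small positive offsets.
    """
    p = params
    n = p.n
    Lx = p.x_max - p.x_min
    xg = p.x_min + Lx * np.arange(n) / n
    if init is None:
        rng = np.random.default_rng(seed)
        def bumps(base, amp):
            out = np.full(n, base)
            for _ in range(3):
                c = rng.uniform(p.x_min + 2, p.x_max - 2)
                w = rng.uniform(0.8, 2.0)
                out = out + amp * rng.uniform(0.5, 1.0) * np.exp(
                    -((xg - c) / w) ** 2)
            return out
        init = (bumps(0.3, 0.4), bumps(0.2, 0.3), bumps(0.1, 0.2),
                bumps(0.1, 0.2))
    fields0 = [np.asarray(f, dtype=float) for f in init]
    k = 2 * np.pi * np.fft.fftfreq(n, d=Lx / n)
    k2 = -(k**2)
    Ds = [p.Dx / p.Du, p.Dz / p.Du, p.Ds / p.Du, p.Du / p.Du]

    def rhs(_t, y):
        x, z, s, u = y.reshape(4, n)
        rx, rz, rs, ru = bz_reaction_rhs(x, z, s, u, p)
        out = []
        for field, r, D in zip((x, z, s, u), (rx, rz, rs, ru), Ds):
            lap = np.real(np.fft.ifft(k2 * np.fft.fft(field)))
            out.append(r + D * lap)
        return np.concatenate(out)

    t_store = np.arange(0.0, p.T + 1e-12, p.dt * store_every)
    sol = solve_ivp(rhs, (0.0, p.T), np.concatenate(fields0), t_eval=t_store,
                    rtol=1e-8, atol=1e-10, method="RK45",
                    max_step=10 * p.dt)
    if not sol.success:
        raise RuntimeError(f"BZ integration failed: {sol.message}")
    names = ("bx", "bz", "bs", "bu")
    fields = {nm: sol.y[i * n:(i + 1) * n, :].T for i, nm in enumerate(names)}
    field_t = {}
    derivs = np.array([rhs(tt, sol.y[:, i])
                       for i, tt in enumerate(sol.t)])  # (nt, 4n)
    for i, nm in enumerate(names):
        field_t[nm + "_t"] = derivs[:, i * n:(i + 1) * n]
    return FieldData(fields=fields, x=xg, t=t_store, periodic=True,
                     field_t=field_t)


# ---------------------------------------------------------------------------
# measurement noise
# ---------------------------------------------------------------------------

def add_noise(data, sigma: float, seed: int):
    """Additive i.i.d. Gaussian measurement noise on states or fields.

    Derivatives and controls are left untouched: noisy derivatives are the
    business of the differentiation recipe of each benchmark.  sigma = 0
    returns a bitwise-identical copy.
    """
    if sigma < 0:
        raise ValueError("noise magnitude must be non-negative")
    rng = np.random.default_rng(seed)
    if isinstance(data, TimeSeriesData):
        X = data.X.copy()
        if sigma > 0:
            X = X + rng.normal(0.0, sigma, size=X.shape)
        return TimeSeriesData(t=data.t.copy(), X=X,
                              Xdot=None if data.Xdot is None else data.Xdot.copy(),
                              U=None if data.U is None else data.U.copy(),
                              state_names=data.state_names,
                              control_names=data.control_names)
    if isinstance(data, FieldData):
        fields = {}
        for nm, arr in data.fields.items():
            noisy = arr.copy()
            if sigma > 0:
                noisy = noisy + rng.normal(0.0, sigma, size=arr.shape)
            fields[nm] = noisy
        return FieldData(fields=fields, x=data.x.copy(), t=data.t.copy(),
                         periodic=data.periodic,
                         field_t={k: v.copy() for k, v in data.field_t.items()})
    raise TypeError(f"cannot add noise to {type(data).__name__}")
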