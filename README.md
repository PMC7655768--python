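# sindypi

Sparse identification of **implicit** dynamical systems — ordinary and
partial differential equations with rational right-hand sides — from
time-series data, via a parallel candidate sweep and constrained sparse
regression.

## The problem

Many systems in biology and chemistry (enzyme kinetics, metabolic
networks, oscillating reactions) have dynamics of the form

```
dx/dt = N(x) / D(x)
```

whose rational right-hand side is *not* a sparse combination of library
functions, so plain sparse regression of `dx/dt` on a candidate library
fails.  Clearing the denominator gives an implicit relation

```
f(x, dx/dt) = 0        i.e.        Theta(X, Xdot) xi = 0
```

which is sparse — but the trivial solution `xi = 0` means it cannot be fit
by ordinary regression, and hunting for sparse vectors in the numerical
null space of `Theta` (the classical implicit approach, via alternating
directions / ADM) collapses under even tiny measurement noise.

This package implements the robust alternative: pick one candidate term
`theta_j` at a time, move it to the left-hand side, and solve the now
*explicit* sparse regression

```
theta_j(X, Xdot) = Theta(X, Xdot | theta_j removed) xi_j
```

for every candidate in parallel, with sequentially thresholded least
squares (STLSQ) over a grid of thresholds `lambda`.  A correct candidate
yields a sparse coefficient vector and an accurate fit; models are scored
on held-out data by the relative error of the predicted derivative,
`||Xdot_t - Xdot_model|| / ||Xdot_t||`, and the winning implicit model is
rearranged into the explicit rational form `dx_k/dt = N_k(x)/D_k(x)` by
collecting the `dx_k`-bearing terms into the denominator.

Also included: the null-space/ADM baseline, an explicit PDE-regression
baseline (no rational terms), total-variation regularized differentiation
for noisy measurements, and simulators with analytic derivatives for the
benchmark systems (Michaelis–Menten kinetics, a seven-state yeast
glycolysis network, a forced pendulum-on-cart, a mounted double pendulum,
a modified Korteweg–de Vries equation, and a simplified
Belousov–Zhabotinsky reaction–diffusion model).

## Worked example

Recover Michaelis–Menten kinetics `dx/dt = j_x - V_max x / (K_m + x)`
from a simulated trajectory:

```python
import sindypi as sp

data = sp.simulate_michaelis_menten()          # x0=0.5, 10 s, dt=1e-3
report = sp.discover_equation(data, sp.systems.mm_library_spec(), "x")
ode = report.winner_ode                        # dx/dt = N(x)/D(x)

print("winner lhs:", report.winner.lhs.label)
print("numerator:  ", [(t.label, round(c, 6)) for t, c in ode.numerator])
print("denominator:", [(t.label, round(c, 6)) for t, c in ode.denominator])
```

prints

```
winner lhs: dx
numerator:   [('1', 0.6), ('x', -3.0)]
denominator: [('1', 1.0), ('x', 3.333333)]
```

i.e. `dx/dt = (0.6 - 3x) / (1 + 3.333x)`, which is exactly
`0.6 - 1.5 x / (0.3 + x)`: influx `j_x = 0.6`, maximum uptake rate
`V_max = 1.5` and half-maximal constant `K_m = 0.3` — the parameters the
data were generated with.  The same machinery handles PDEs: fitting the
modified KdV equation with its rational gain term active recovers
`u_t = (2 g0 - (1+u)(u_xxx + 6 u u_x + 0.1 u)) / (1 + u)` with the
advection coefficient −6 and loss coefficient 0.1 to eight digits.

A command-line interface wraps the main workflows:

```sh
sindypi simulate michaelis-menten --out mm.tsv
sindypi fit --data mm.tsv --state x
sindypi benchmark-noise --repetitions 10
```

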