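"""Implicit PDE identification and the explicit PDE-FIND baseline.

Space-time fields are turned into flattened sample libraries over
{u, u_x, u_xx, u_xxx, u_t, products}, including u_t-bearing implicit
columns, and fitted with the same candidate-sweep machinery as the ODE
case.  The explicit baseline regresses u_t directly on spatial terms and
therefore cannot represent rational right-hand sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .identification import (CandidateModel, RationalODE, sweep_candidates,
                             to_explicit_ode)
from .library import (LibraryMatrix, LibrarySpec, TimeSeriesData,
                      enumerate_terms, evaluate_terms, normalize_columns)
from .selection import SelectionReport
from .solvers import SolverConfig, stlsq

PDE_THRESHOLDS = np.geomspace(1e-4, 1.0, 17)

__all__ = ["FieldData", "spatial_derivatives", "build_pde_library",
           "fit_pde_implicit", "pdefind_baseline", "kdv_library_spec",
           "kdv_implicit_truth", "kdv_explicit_truth"]


@dataclass
class FieldData:
    """Field snapshots u(x, t) (and co-fields) on a uniform space-time grid.

    fields maps name -> (nt, nx) array; field_t optionally carries analytic
    time derivatives under keys like "u_t".
    """

    fields: dict[str, np.ndarray]
    x: np.ndarray
    t: np.ndarray
    periodic: bool = True
    field_t: dict[str, np.ndarray] = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        shapes = {arr.shape for arr in self.fields.values()}
        shapes |= {arr.shape for arr in self.field_t.values()}
        if len(shapes) != 1:
            raise ValueError("all fields must share one (nt, nx) shape")
        (shape,) = shapes
        if shape != (self.t.size, self.x.size):
            raise ValueError("field shape does not match the (t, x) grids")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def spatial_derivatives(data: FieldData, order: int, name: str = "u",
                        scheme: str = "spectral",
                        max_order: int = 4) -> dict[str, np.ndarray]:
    """Spatial derivatives of one field up to the requested order.

    Spectral differentiation requires a periodic domain; the alternative is
    a fourth-order central finite-difference stencil (periodic wrap).
    """
    if order > max_order:
        raise ValueError(f"order {order} exceeds configured max {max_order}")
    u = data.fields[name]
    out = {}
    if scheme == "spectral":
        if not data.periodic:
            raise ValueError("spectral derivatives need a periodic domain")
        k = 2 * np.pi * np.fft.fftfreq(data.x.size, d=data.dx)
        spec = np.fft.fft(u, axis=1)
        for o in range(1, order + 1):
            out[name + "_" + "x" * o] = np.real(
                np.fft.ifft((1j * k) ** o * spec, axis=1))
    elif scheme == "fd":
        cur = u
        h = data.dx
        for o in range(1, order + 1):
            # 4th-order central first derivative, applied repeatedly
            cur = (-np.roll(cur, -2, axis=1) + 8 * np.roll(cur, -1, axis=1)
                   - 8 * np.roll(cur, 1, axis=1)
                   + np.roll(cur, 2, axis=1)) / (12 * h)
            out[name + "_" + "x" * o] = cur
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return out


def kdv_library_spec(degree: int = 2, max_spatial_order: int = 3,
                     include_ut: bool = True) -> LibrarySpec:
    """Default vocabulary {1, u, u^2} x {1, u_x, u_xx, u_xxx[, u_t]}."""
    derivs = tuple("u_" + "x" * o for o in range(1, max_spatial_order + 1))
    if include_ut:
        derivs = derivs + ("u_t",)
    return LibrarySpec(state_names=("u",), derivative_names=derivs,
                       degree=degree)


def kdv_implicit_truth(gamma: float, g0: float) -> frozenset[str]:
    """Cleared-denominator support of the modified KdV equation.

    For g0 > 0:  u_t (1+u) = -(1+u)(u_xxx + 6 u u_x + gamma u) + 2 g0.
    For g0 = 0 the dynamics are explicit and the minimal relation drops the
    denominator factor.
    """
    if g0 == 0.0:
        support = {"u_t", "u_xxx", "u*u_x"}
        if gamma != 0.0:
            support.add("u")
        return frozenset(support)
    support = {"u_t", "u*u_t", "u_xxx", "u*u_xxx", "u*u_x", "u^2*u_x", "1"}
    if gamma != 0.0:
        support |= {"u", "u^2"}
    return frozenset(support)


def kdv_explicit_truth(gamma: float) -> frozenset[str]:
    support = {"u_xxx", "u*u_x"}
    if gamma != 0.0:
        support.add("u")
    return frozenset(support)


@dataclass
class PDESamples:
    """Flattened space-time samples: features container plus the u_t column."""

    features: TimeSeriesData
    ut: np.ndarray
    library: LibraryMatrix


def build_pde_library(data: FieldData, spec: LibrarySpec | None = None,
                      name: str = "u", scheme: str = "spectral",
                      subsample: int | None = 10_000, seed: int = 0,
                      ut_source: str = "auto", time_trim: int = 3,
                      holdout: float = 0.2) -> tuple[PDESamples, PDESamples]:
    """Evaluate the PDE library on flattened samples; chronological split.

    u_t comes from the simulator's analytic residual when present
    (``ut_source='auto'``) else from second-order finite differences in t,
    trimming ``time_trim`` slices at each (non-periodic) time boundary.
    Returns (train samples, validation samples).
    """
    spec = spec or kdv_library_spec()
    if "u_t" not in spec.derivative_names:
        raise ValueError("spec must include u_t for implicit fitting")
    u = data.fields[name]
    max_order = max(len(d) - len(name) - 1 for d in spec.derivative_names
                    if d.startswith(name + "_") and set(d[len(name) + 1:]) == {"x"})
    derivs = spatial_derivatives(data, max_order, name=name, scheme=scheme)

    key = name + "_t"
    if ut_source == "auto" and key in data.field_t:
        ut = data.field_t[key]
        rows = np.arange(data.t.size)
    else:
        ut = np.gradient(u, data.dt, axis=0, edge_order=2)
        rows = np.arange(time_trim, data.t.size - time_trim)
    u = u[rows]
    ut = ut[rows]
    derivs = {k: v[rows] for k, v in derivs.items()}

    nt = rows.size
    cut = max(1, min(nt - 1, int(round((1.0 - holdout) * nt))))
    rng = np.random.default_rng(seed)

    def pack(sl):
        cols = {name: u[sl].ravel(), key: ut[sl].ravel()}
        for k, v in derivs.items():
            cols[k] = v[sl].ravel()
        m = cols[name].size
        if subsample is not None and subsample < m:
            idx = np.sort(rng.choice(m, size=subsample, replace=False))
            cols = {k: v[idx] for k, v in cols.items()}
            m = subsample
        names = [name] + list(derivs.keys()) + [key]
        X = np.column_stack([cols[k] for k in names])
        container = TimeSeriesData(t=np.arange(m, dtype=float), X=X,
                                   state_names=tuple(names))
        lib = evaluate_terms(enumerate_terms(spec), container)
        return PDESamples(features=container, ut=cols[key], library=lib)

    return pack(slice(0, cut)), pack(slice(cut, nt))


def _pde_validation_error(ode: RationalODE, valid: PDESamples) -> float:
    pred, ok = ode.evaluate(valid.features)
    if np.sum(ok) < 0.5 * ok.size:
        return float("inf")
    truth = valid.ut
    denom = np.linalg.norm(truth[ok])
    if denom == 0.0:
        return float("inf")
    return float(np.linalg.norm(pred[ok] - truth[ok]) / denom)


def fit_pde_implicit(train: PDESamples, valid: PDESamples,
                     candidates: list[str] | None = None,
                     thresholds=None,
                     config: SolverConfig | None = None,
                     tie_band: float = 3.0):
    """Candidate sweep over u_t-bearing left-hand sides, validation-selected.

    Returns (SelectionReport, explicit RationalODE for u_t = N/D).
    """
    candidates = candidates if candidates is not None else ["u_t", "u*u_t"]
    if not candidates:
        raise ValueError("candidate list is empty")
    thresholds = thresholds if thresholds is not None else PDE_THRESHOLDS
    config = config or SolverConfig()
    idx = [train.library.column(c) for c in candidates]
    models = sweep_candidates(train.library, idx, thresholds, config)

    rows, odes = [], []
    for i, model in enumerate(models):
        if model.failed or model.coefficients is None:
            degree = 0
        else:
            degree = model.lhs.degree + sum(
                t.degree for t, c in zip(model.terms, model.coefficients)
                if c != 0.0)
        row = {"index": i, "lhs": model.lhs.label, "lambda": model.threshold,
               "sparsity": model.sparsity, "degree": degree,
               "residual": model.residual,
               "error": np.inf, "failed": model.failed, "winner": False}
        ode = None
        if not model.failed:
            try:
                ode = to_explicit_ode(model, "u", deriv_name="u_t",
                                      train_data=train.features)
                row["error"] = _pde_validation_error(ode, valid)
            except Exception as exc:
                row["failed"], row["note"] = True, str(exc)
                ode = None
        if not np.isfinite(row["error"]):
            row["failed"] = True
        rows.append(row)
        odes.append(ode)
    viable = [r for r in rows if not r["failed"]]
    if not viable:
        raise ValueError("all PDE candidate fits failed")
    # same near-tie rule as ODE selection: sparse-and-accurate wins;
    # errors below ~single precision count as exact ties
    best_err = min(r["error"] for r in viable)
    band = max(tie_band * best_err, 1e-6)
    tied = [r for r in viable if r["error"] <= band]
    nonempty = [r for r in tied if r["sparsity"] > 0]
    if nonempty:
        tied = nonempty
    best = min(tied, key=lambda r: (r["sparsity"], r["degree"], r["index"]))
    best["winner"] = True
    best_i = best["index"]
    report = SelectionReport(table=rows, winner=models[best_i],
                             winner_ode=odes[best_i], criterion="derivative",
                             split="80/20 chronological (time slices)")
    return report, odes[best_i]


def pdefind_baseline(train: PDESamples, valid: PDESamples,
                     thresholds=None,
                     config: SolverConfig | None = None) -> CandidateModel:
    """Explicit sparse regression of u_t on spatial library terms only.

    u_t-bearing columns are excluded from the regressors (using the exact
    target as a regressor would be leakage, and rational terms are simply
    not representable); the threshold is chosen on the validation split.
    """
    thresholds = thresholds if thresholds is not None else PDE_THRESHOLDS
    config = config or SolverConfig()
    keep = [i for i, t in enumerate(train.library.terms)
            if not t.contains("u_t")]
    if len(keep) == len(train.library.terms):
        raise ValueError("library contains no u_t column to regress on")
    sub = LibraryMatrix(train.library.values[:, keep],
                        [train.library.terms[i] for i in keep])
    vsub = LibraryMatrix(valid.library.values[:, keep],
                         [valid.library.terms[i] for i in keep])
    target = train.ut
    tnorm = np.linalg.norm(target)
    nl = normalize_columns(sub)
    usable = ~nl.zero_columns

    best = None
    for lam in np.atleast_1d(thresholds):
        cfg = SolverConfig(threshold=float(lam), max_iter=config.max_iter,
                           ridge=config.ridge)
        fit = stlsq(nl.values[:, usable], target / tnorm, cfg)
        coefs = np.zeros(sub.p)
        coefs[usable] = fit.coefficients * tnorm / nl.norms[usable]
        verr = float(np.linalg.norm(valid.ut - vsub.values @ coefs)
                     / max(np.linalg.norm(valid.ut), 1e-300))
        key = (verr, int(np.count_nonzero(coefs)))
        if best is None or key < best[0]:
            best = (key, coefs, float(lam))
    _, coefs, lam = best
    ut_term = train.library.terms[train.library.column("u_t")]
    model = CandidateModel(lhs=ut_term, terms=list(sub.terms),
                           coefficients=coefs, threshold=lam)
    model.diagnostics["validation_error"] = best[0][0]
    return model
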