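"""SINDy-PI core: per-candidate implicit fits and rational-ODE recovery.

The implicit relation Theta(X, Xdot) xi = 0 is made explicit by moving one
candidate column theta_j to the left-hand side and sparsely regressing it on
the rest.  Models fitted with derivative-bearing candidates are then
rearranged into explicit rational form xdot_k = N_k(x)/D_k(x), simulated,
and scored structurally against a known support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .library import (LibraryMatrix, TermDescriptor, TimeSeriesData,
                      evaluate_terms, normalize_columns, split_candidate)
from .solvers import SolverConfig, stlsq

__all__ = ["CandidateModel", "RationalODE", "StructureScore", "fit_candidate",
           "sweep_candidates", "derivative_candidates", "to_explicit_ode",
           "simulate_identified", "structure_error"]

# coefficients with |xi| below this fraction of the largest are treated as
# numerically zero when reading off a support
SUPPORT_TOL = 1e-10


class DegenerateLhsError(ValueError):
    """Candidate left-hand-side column is identically zero on the data."""


class NotReducibleError(ValueError):
    """Implicit model cannot be rearranged into xdot_k = N/D form."""


@dataclass
class CandidateModel:
    """A sparse implicit model for one candidate left-hand side."""

    lhs: TermDescriptor
    terms: list[TermDescriptor]
    coefficients: np.ndarray | None
    threshold: float
    residual: float = np.inf
    error: str | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return self.error is not None

    @property
    def sparsity(self) -> int:
        if self.coefficients is None:
            return 0
        return int(np.count_nonzero(self.coefficients))

    @property
    def rhs_support(self) -> list[str]:
        if self.coefficients is None:
            return []
        return [t.label for t, c in zip(self.terms, self.coefficients)
                if c != 0.0]

    @property
    def implicit_support(self) -> frozenset[str]:
        """Support of the implicit relation: lhs term plus active rhs terms."""
        return frozenset([self.lhs.label, *self.rhs_support])

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset([self.lhs.label, *(t.label for t in self.terms)])


@dataclass
class StructureScore:
    """Counts of incorrectly added and deleted terms versus the truth."""

    added: int
    deleted: int

    @property
    def total(self) -> int:
        return self.added + self.deleted


@dataclass
class RationalODE:
    """Explicit rational right-hand side xdot_k = N_k(x) / D_k(x)."""

    state_name: str
    numerator: list[tuple[TermDescriptor, float]]
    denominator: list[tuple[TermDescriptor, float]]
    eps_d: float = 0.0

    def __post_init__(self) -> None:
        if not self.denominator:
            raise NotReducibleError("denominator is identically zero")

    def _eval_side(self, side, resolve) -> np.ndarray:
        out = None
        for term, coef in side:
            val = coef * term.evaluate(resolve)
            out = val if out is None else out + val
        if out is None:
            return np.zeros_like(resolve(None), dtype=float)
        return out

    def evaluate(self, data: TimeSeriesData):
        """Predicted derivative on sampled states.

        Returns (prediction, valid mask); samples where |D| falls below the
        safeguard eps_d are masked out rather than producing blow-ups.
        """
        m = data.n_samples

        def resolve(name):
            if name is None:
                return np.zeros(m)
            return data.channel(name)

        num = self._eval_side(self.numerator, resolve)
        den = self._eval_side(self.denominator, resolve)
        guard = self.eps_d if self.eps_d > 0 else 1e-12 * np.max(
            np.abs(den) + 1e-300)
        valid = np.abs(den) >= guard
        pred = np.zeros(m)
        pred[valid] = num[valid] / den[valid]
        return pred, valid

    def rhs_value(self, state_values: dict[str, float]) -> float:
        def resolve(name):
            if name is None:
                return np.zeros(1)
            return np.asarray([state_values[name]])

        num = float(self._eval_side(self.numerator, resolve)[0])
        den = float(self._eval_side(self.denominator, resolve)[0])
        return num / den

    def coefficient(self, label: str, side: str = "numerator") -> float:
        """Coefficient attached to a term label (0 if absent)."""
        entries = self.numerator if side == "numerator" else self.denominator
        for term, coef in entries:
            if term.label == label:
                return coef
        return 0.0

    @property
    def support(self) -> frozenset[str]:
        return frozenset(t.label for t, c in self.numerator if c != 0.0) | \
            frozenset(t.label for t, c in self.denominator if c != 0.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _polish_fit(A: np.ndarray, b: np.ndarray, support: np.ndarray,
                degrees: np.ndarray | None = None,
                tol_factor: float = 1.1):
    """Greedy backward pruning of a regression support.

    Drops one active column at a time as long as the refit residual grows
    by no more than ``tol_factor`` (i.e. the drop is essentially free, with
    a small absolute floor).  Among acceptable drops the highest-degree
    column goes first.  This strips support members that only entered
    through a redundant representation (e.g. a monomial multiple of the
    minimal implicit relation), which plain thresholding cannot
    distinguish, and steers ties toward the lowest-degree relation.
    """
    support = support.copy()
    p = A.shape[1]
    if not support.any():
        return support, np.zeros(p)
    if degrees is None:
        degrees = np.zeros(p)

    # Gram form: each trial refit costs O(k^3) instead of O(m k^2)
    AtA = A.T @ A
    Atb = A.T @ b
    btb = float(b @ b)

    def refit(mask):
        idx = np.flatnonzero(mask)
        G = AtA[np.ix_(idx, idx)]
        try:
            sol = np.linalg.solve(G, Atb[idx])
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(G, Atb[idx], rcond=None)[0]
        xi = np.zeros(p)
        xi[idx] = sol
        r2 = btb - 2.0 * sol @ Atb[idx] + sol @ G @ sol
        return xi, float(np.sqrt(max(r2, 0.0)))

    xi, resid = refit(support)
    # floor sits above the ~sqrt(eps) cancellation noise of the Gram-form
    # residual so that dropping a redundant column of an exact fit counts
    # as free
    floor = 1e-7 * np.linalg.norm(b)
    while support.sum() > 1:
        best = None
        for jj in np.flatnonzero(support):
            trial = support.copy()
            trial[jj] = False
            _, r_t = refit(trial)
            if r_t <= tol_factor * resid + floor:
                key = (-degrees[jj], r_t)
                if best is None or key < best[0]:
                    best = (key, jj)
        if best is None:
            break
        support[best[1]] = False
        xi, resid = refit(support)
    return support, xi


def fit_candidate(lib: LibraryMatrix, j: int, config: SolverConfig,
                  normalize: bool = True,
                  polish: bool = True) -> CandidateModel:
    """Fit one candidate: remove column j, sparse-regress it on the rest.

    With ``normalize`` (the default) the reduced columns are scaled to unit
    norm and the target to unit norm before thresholding, so the threshold
    lambda acts on dimensionless coefficients; returned coefficients are
    mapped back to the original scale.  ``polish`` applies a greedy
    backward pruning pass after thresholding (see :func:`_polish_fit`).
    """
    lhs_term, target, reduced = split_candidate(lib, j)
    tnorm = float(np.linalg.norm(target))
    if tnorm == 0.0:
        raise DegenerateLhsError(
            f"degenerate lhs: candidate {lhs_term.label!r} is zero on data")
    if reduced.p == 0:
        raise ValueError("no remaining regressors after split")
    if normalize:
        nl = normalize_columns(reduced)
        usable = ~nl.zero_columns
        A, bvec = nl.values[:, usable], target / tnorm
        fit = stlsq(A, bvec, config)
        xi_scaled = fit.coefficients
        if polish and fit.support.any():
            degs = np.array([t.degree for t in reduced.terms],
                            dtype=float)[usable]
            _, xi_scaled = _polish_fit(A, bvec, fit.support, degrees=degs)
        coefs = np.zeros(reduced.p)
        coefs[usable] = xi_scaled * tnorm / nl.norms[usable]
        scaled_coefs = np.zeros(reduced.p)
        scaled_coefs[usable] = xi_scaled
    else:
        fit = stlsq(reduced.values, target, config)
        xi = fit.coefficients
        if polish and fit.support.any():
            degs = np.array([t.degree for t in reduced.terms], dtype=float)
            _, xi = _polish_fit(reduced.values, target, fit.support,
                                degrees=degs)
        coefs = xi
        scaled_coefs = coefs
    resid = float(np.linalg.norm(target - reduced.values @ coefs) / tnorm)
    return CandidateModel(
        lhs=lhs_term, terms=list(reduced.terms), coefficients=coefs,
        threshold=config.threshold, residual=resid,
        diagnostics={"iterations": fit.iterations, "converged": fit.converged,
                     "empty": fit.empty, "normalized": normalize,
                     "scaled_coefficients": scaled_coefs})


def derivative_candidates(lib: LibraryMatrix, deriv_name: str) -> list[int]:
    """Indices of candidate lhs terms of the form xdot_k * theta(x).

    Terms linear in ``deriv_name`` and free of any other derivative factor,
    per the rational-dynamics candidate restriction.
    """
    out = []
    for i, term in enumerate(lib.terms):
        if term.exponent(deriv_name) != 1:
            continue
        others = [v for v, _ in term.factors
                  if v != deriv_name and v.startswith("d")]
        if others:
            continue
        out.append(i)
    return out


def sweep_candidates(lib: LibraryMatrix, candidates, thresholds,
                     config: SolverConfig, normalize: bool = True,
                     n_jobs: int = 1) -> list[CandidateModel]:
    """Fit every (candidate, lambda) pair; a pure, order-independent map.

    Per-fit failures are captured on the returned models rather than
    aborting the sweep.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set is empty")
    thresholds = [float(l) for l in np.atleast_1d(thresholds)]

    def one(j, lam):
        cfg = SolverConfig(threshold=lam, max_iter=config.max_iter,
                           ridge=config.ridge,
                           nullspace_cutoff=config.nullspace_cutoff,
                           adm_restarts=config.adm_restarts,
                           adm_prune=config.adm_prune, seed=config.seed)
        try:
            return fit_candidate(lib, j, cfg, normalize=normalize)
        except Exception as exc:  # captured per item by contract
            return CandidateModel(lhs=lib.terms[j], terms=[],
                                  coefficients=None, threshold=lam,
                                  error=str(exc))

    jobs = [(j, lam) for j in candidates for lam in thresholds]
    if n_jobs != 1:
        from joblib import Parallel, delayed
        return list(Parallel(n_jobs=n_jobs, backend="threading")(
            delayed(one)(j, lam) for j, lam in jobs))
    return [one(j, lam) for j, lam in jobs]


# ---------------------------------------------------------------------------
# implicit -> explicit rational form
# ---------------------------------------------------------------------------

def to_explicit_ode(model: CandidateModel, state_name: str,
                    deriv_name: str | None = None,
                    train_data: TimeSeriesData | None = None) -> RationalODE:
    """Rearrange an implicit model into xdot_k = N_k(x)/D_k(x).

    Terms carrying the derivative factor (to power exactly 1) contribute to
    the denominator with the factor stripped; the remainder forms the
    numerator.  The result is normalized so the denominator's constant
    coefficient is 1 (or its first coefficient, if no constant term).
    """
    if model.failed or model.coefficients is None:
        raise NotReducibleError(f"model failed: {model.error}")
    deriv_name = deriv_name or "d" + state_name

    entries = [(model.lhs, 1.0)]
    entries += [(t, -c) for t, c in zip(model.terms, model.coefficients)
                if c != 0.0]

    den: dict[TermDescriptor, float] = {}
    num: dict[TermDescriptor, float] = {}
    for term, coef in entries:
        e = term.exponent(deriv_name)
        other_derivs = [v for v, _ in term.factors
                        if v != deriv_name and v.startswith("d")
                        and v in _deriv_vocabulary(model)]
        if other_derivs:
            raise NotReducibleError(
                f"term {term.label!r} contains another derivative")
        if e > 1:
            raise NotReducibleError(
                f"term {term.label!r} is nonlinear in {deriv_name!r}")
        if e == 1:
            stripped = term.without(deriv_name)
            den[stripped] = den.get(stripped, 0.0) + coef
        else:
            num[term] = num.get(term, 0.0) - coef
    den = {t: c for t, c in den.items() if c != 0.0}
    if not den:
        raise NotReducibleError(
            f"no {deriv_name!r}-bearing terms: model is not reducible")

    # normalize the denominator: constant coefficient -> 1 when present
    const = den.get(TermDescriptor(), None)
    scale = const if const else next(iter(
        sorted(den.items(), key=lambda tc: (tc[0].degree, tc[0].label))))[1]
    den = [(t, c / scale) for t, c in sorted(
        den.items(), key=lambda tc: (tc[0].degree, tc[0].label))]
    num = [(t, c / scale) for t, c in sorted(
        num.items(), key=lambda tc: (tc[0].degree, tc[0].label)) if c != 0.0]

    ode = RationalODE(state_name=state_name, numerator=num, denominator=den)
    data = train_data
    if data is None and model.diagnostics.get("source") is not None:
        data = model.diagnostics["source"]
    if data is not None:
        def resolve(name):
            if name is None:
                return np.zeros(data.n_samples)
            return data.channel(name)
        dvals = ode._eval_side(ode.denominator, resolve)
        ode.eps_d = 1e-8 * float(np.max(np.abs(dvals)))
    return ode


def _deriv_vocabulary(model: CandidateModel) -> set[str]:
    vocab = set()
    for term in [model.lhs, *model.terms]:
        for v, _ in term.factors:
            if v.startswith("d"):
                vocab.add(v)
    return vocab


# ---------------------------------------------------------------------------
# simulation of identified models
# ---------------------------------------------------------------------------

def simulate_identified(odes: list[RationalODE], x0, t,
                        control_fn=None, control_names: tuple[str, ...] = (),
                        rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate xdot_k = N_k/D_k; aborts cleanly near denominator zeros.

    Returns (TimeSeriesData over the covered time grid, completed flag).
    """
    t = np.asarray(t, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    names = tuple(o.state_name for o in odes)
    eps = np.array([max(o.eps_d, 1e-12) for o in odes])

    def resolve_at(x, tt):
        vals = dict(zip(names, x))
        if control_fn is not None:
            u = np.atleast_1d(control_fn(tt))
            for nm, uv in zip(control_names, u):
                vals[nm] = uv
        return vals

    def rhs(tt, x):
        vals = resolve_at(x, tt)
        return [o.rhs_value(vals) for o in odes]

    def den_guard(tt, x):
        vals = resolve_at(x, tt)
        margins = []
        for o, e in zip(odes, eps):
            def resolve(name, _vals=vals):
                if name is None:
                    return np.zeros(1)
                return np.asarray([_vals[name]])
            margins.append(abs(float(o._eval_side(o.denominator, resolve)[0])) - e)
        return min(margins)

    den_guard.terminal = True
    den_guard.direction = -1

    sol = solve_ivp(rhs, (t[0], t[-1]), x0, t_eval=t, rtol=rtol, atol=atol,
                    events=den_guard, dense_output=False)
    completed = sol.status == 0 and sol.t.size == t.size
    tt = sol.t
    X = sol.y.T
    if tt.size < 2:  # degenerate: keep at least the initial point
        tt = t[:1]
        X = x0[None, :]
    Xdot = np.array([rhs(ti, xi) for ti, xi in zip(tt, X)])
    U = None
    if control_fn is not None:
        U = np.array([np.atleast_1d(control_fn(ti)) for ti in tt])
    return TimeSeriesData(t=tt, X=X, Xdot=Xdot, U=U, state_names=names,
                          control_names=control_names), completed


# ---------------------------------------------------------------------------
# structural scoring
# ---------------------------------------------------------------------------

def structure_error(model, truth_support) -> StructureScore:
    """Added/deleted term counts of a fitted support versus the truth.

    ``model`` may be a CandidateModel (implicit support is scored), a
    RationalODE, or any iterable of term labels.  Comparison is on supports
    only -- implicit relations are defined up to scale.
    """
    truth = frozenset(truth_support)
    if isinstance(model, CandidateModel):
        fit = model.implicit_support
        vocab = model.vocabulary
        if not truth <= vocab:
            missing = sorted(truth - vocab)
            raise ValueError(f"truth labels not in model vocabulary: {missing}")
    elif isinstance(model, RationalODE):
        fit = model.support
    else:
        fit = frozenset(model)
    return StructureScore(added=len(fit - truth), deleted=len(truth - fit))
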