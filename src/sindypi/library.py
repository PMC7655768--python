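"""Candidate-function libraries for implicit sparse regression.

This module builds and evaluates the library Theta(X, Xdot, U): symbolic
term descriptors (monomials in states, derivatives and controls, optionally
multiplied by sin/cos factors), their deterministic enumeration from a
:class:`LibrarySpec`, and their evaluation on trajectory data into a
:class:`LibraryMatrix` whose columns feed the sparse solvers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesData",
    "TermDescriptor",
    "LibrarySpec",
    "LibraryMatrix",
    "enumerate_terms",
    "evaluate_terms",
    "split_candidate",
    "normalize_columns",
    "CONSTANT_TERM",
]


class LibraryError(ValueError):
    """Invalid library specification or evaluation request."""


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesData:
    """Sampled multivariate trajectory with optional derivatives and controls.

    Parameters
    ----------
    t : (m,) strictly increasing time grid in seconds.
    X : (m, n) state samples, one column per state.
    Xdot : (m, n) state derivatives, optional (may be computed later).
    U : (m, q) control inputs, optional.
    state_names : names for the state columns; derivatives are addressed
        as ``"d" + name``.
    control_names : names for the control columns.
    """

    t: np.ndarray
    X: np.ndarray
    Xdot: np.ndarray | None = None
    U: np.ndarray | None = None
    state_names: tuple[str, ...] = ()
    control_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.t.shape[0]:
            self.X = self.X.T
        m, n = self.X.shape
        if self.t.shape != (m,):
            raise LibraryError("time grid and state rows disagree")
        if m > 1 and not np.all(np.diff(self.t) > 0):
            raise LibraryError("time grid must be strictly increasing")
        if not self.state_names:
            self.state_names = tuple(f"x{i + 1}" for i in range(n))
        if len(self.state_names) != n:
            raise LibraryError("state_names length mismatch")
        if self.Xdot is not None:
            self.Xdot = np.atleast_2d(np.asarray(self.Xdot, dtype=float))
            if self.Xdot.shape != self.X.shape:
                self.Xdot = self.Xdot.T
            if self.Xdot.shape != self.X.shape:
                raise LibraryError("Xdot shape mismatch")
        if self.U is not None:
            self.U = np.asarray(self.U, dtype=float)
            if self.U.ndim == 1:
                self.U = self.U[:, None]
            if self.U.shape[0] != m:
                raise LibraryError("control rows mismatch")
            if not self.control_names:
                self.control_names = tuple(
                    f"u{i + 1}" for i in range(self.U.shape[1])
                )
        for arr, what in ((self.t, "t"), (self.X, "X"), (self.Xdot, "Xdot"),
                          (self.U, "U")):
            if arr is not None and not np.all(np.isfinite(arr)):
                raise LibraryError(f"non-finite values in {what}")

    # -- channel resolution --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return the sampled signal for a state, derivative or control name."""
        if name in self.state_names:
            return self.X[:, self.state_names.index(name)]
        if name.startswith("d") and name[1:] in self.state_names:
            if self.Xdot is None:
                raise LibraryError(
                    f"term references derivative {name!r} but no derivatives "
                    "are attached; differentiate first"
                )
            return self.Xdot[:, self.state_names.index(name[1:])]
        if self.control_names and name in self.control_names:
            return self.U[:, self.control_names.index(name)]
        raise LibraryError(f"unknown variable {name!r}")

    def rows(self, idx: np.ndarray) -> "TimeSeriesData":
        """Row-subsampled copy (used by data-efficiency benchmarks)."""
        return TimeSeriesData(
            t=self.t[idx],
            X=self.X[idx],
            Xdot=None if self.Xdot is None else self.Xdot[idx],
            U=None if self.U is None else self.U[idx],
            state_names=self.state_names,
            control_names=self.control_names,
        )

    def split(self, train_fraction: float = 0.8) -> tuple["TimeSeriesData", "TimeSeriesData"]:
        """Chronological train/validation split (default 80/20)."""
        cut = int(round(train_fraction * self.n_samples))
        cut = min(max(cut, 1), self.n_samples - 1)
        order = np.arange(self.n_samples)
        return self.rows(order[:cut]), self.rows(order[cut:])



# ---------------------------------------------------------------------------
# term descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermDescriptor:
    """One candidate function: a product of variable powers and trig factors.

    ``factors`` holds (variable id, exponent) pairs over states, derivatives
    and controls; ``trig`` holds (function, variable id) pairs, repeated for
    powers (e.g. cos^2).  The empty descriptor is the constant term 1.
    """

    factors: tuple[tuple[str, int], ...] = ()
    trig: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors",
                           tuple(sorted((v, int(e)) for v, e in self.factors
                                        if int(e) != 0)))
        object.__setattr__(self, "trig", tuple(sorted(self.trig)))
        for v, e in self.factors:
            if e < 0:
                raise LibraryError(f"negative exponent on {v!r}")
        for fn, _ in self.trig:
            if fn not in ("sin", "cos"):
                raise LibraryError(f"unsupported trig function {fn!r}")

    # -- structure ------------------------------------------------------------
    @property
    def degree(self) -> int:
        return sum(e for _, e in self.factors) + len(self.trig)

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(v for v, _ in self.factors) | frozenset(
            v for _, v in self.trig)

    def exponent(self, var: str) -> int:
        return dict(self.factors).get(var, 0)

    def contains(self, var: str) -> bool:
        return self.exponent(var) > 0

    @property
    def label(self) -> str:
        parts = [f"{v}^{e}" if e > 1 else v for v, e in self.factors]
        for (fn, v), grp in itertools.groupby(self.trig):
            k = len(list(grp))
            parts.append(f"{fn}({v})" + (f"^{k}" if k > 1 else ""))
        return "*".join(parts) if parts else "1"

    def __mul__(self, other: "TermDescriptor") -> "TermDescriptor":
        exps: dict[str, int] = dict(self.factors)
        for v, e in other.factors:
            exps[v] = exps.get(v, 0) + e
        return TermDescriptor(tuple(exps.items()), self.trig + other.trig)

    def without(self, var: str) -> "TermDescriptor":
        """Strip one power of ``var`` (used when clearing a derivative factor)."""
        exps = dict(self.factors)
        if exps.get(var, 0) < 1:
            raise LibraryError(f"term {self.label!r} has no factor {var!r}")
        exps[var] -= 1
        return TermDescriptor(tuple(exps.items()), self.trig)

    def evaluate(self, resolve) -> np.ndarray:
        """Pointwise product of factors; ``resolve`` maps name -> array."""
        out = None
        for v, e in self.factors:
            col = resolve(v) ** e
            out = col if out is None else out * col
        for fn, v in self.trig:
            col = np.sin(resolve(v)) if fn == "sin" else np.cos(resolve(v))
            out = col if out is None else out * col
        if out is None:
            base = resolve(None)
            return np.ones_like(base, dtype=float)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TermDescriptor({self.label!r})"


CONSTANT_TERM = TermDescriptor()


def _term_sort_key(term: TermDescriptor):
    # graded lexicographic: total degree, then the expanded variable token
    # sequence -- deterministic across runs and platforms
    tokens = []
    for v, e in term.factors:
        tokens.extend([v] * e)
    for fn, v in term.trig:
        tokens.append(f"{fn}({v})")
    return (term.degree, tuple(sorted(tokens)))


# ---------------------------------------------------------------------------
# specification and enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibrarySpec:
    """Configuration of a candidate library.

    degree : polynomial degree cap over states and controls.
    trig_states : subset of state names that may appear inside sin/cos.
    trig_degree : cap on total trig degree per term (sin*cos products etc.).
    derivative_multiplicity : max number of derivative factors per term
        (1 keeps every term affine in each derivative, as the rational-ODE
        reconstruction requires).
    max_exponent : optional per-variable exponent caps.
    extra_monomials : exponent maps appended verbatim beyond the degree cap
        (still crossed with derivative factors).
    deriv_cofactor_degree : optional lower degree cap for the polynomial
        cofactor of derivative-bearing terms.  Capping it below ``degree``
        keeps monomial multiples of a cleared-denominator relation out of
        the library span, which would otherwise make the sparsest implicit
        relation non-unique.
    """

    state_names: tuple[str, ...]
    derivative_names: tuple[str, ...] | None = None
    control_names: tuple[str, ...] = ()
    degree: int = 2
    trig_states: tuple[str, ...] = ()
    trig_degree: int = 2
    derivative_multiplicity: int = 1
    include_constant: bool = True
    max_exponent: tuple[tuple[str, int], ...] = ()
    extra_monomials: tuple[tuple[tuple[str, int], ...], ...] = ()
    deriv_cofactor_degree: int | None = None

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise LibraryError("degree cap must be >= 0")
        if not set(self.trig_states) <= set(self.state_names):
            raise LibraryError("trig_states must be a subset of state_names")
        if self.derivative_names is None:
            object.__setattr__(
                self, "derivative_names",
                tuple("d" + s for s in self.state_names))


def _poly_monomials(variables, degree, caps):
    """All exponent maps with total degree <= cap, honoring per-var caps."""
    out = [()]
    for d in range(1, degree + 1):
        for combo in itertools.combinations_with_replacement(variables, d):
            exps: dict[str, int] = {}
            for v in combo:
                exps[v] = exps.get(v, 0) + 1
            if any(e > caps.get(v, degree) for v, e in exps.items()):
                continue
            out.append(tuple(sorted(exps.items())))
    return out


def enumerate_terms(spec: LibrarySpec) -> list[TermDescriptor]:
    """Enumerate the candidate terms of a library specification.

    Ordering is graded lexicographic (total degree, then variable ids) with
    the constant term first, so candidate indices are reproducible.
    """
    caps = dict(spec.max_exponent)
    poly = _poly_monomials(
        tuple(spec.state_names) + tuple(spec.control_names), spec.degree, caps)
    poly = list(poly) + [tuple(sorted(m)) for m in spec.extra_monomials]

    trig_sets: list[tuple[tuple[str, str], ...]] = [()]
    trig_vocab = [(fn, v) for v in spec.trig_states for fn in ("sin", "cos")]
    for d in range(1, spec.trig_degree + 1):
        for combo in itertools.combinations_with_replacement(trig_vocab, d):
            # sin^2(v) = 1 - cos^2(v): keeping both would make the library
            # exactly rank-deficient, so same-variable sin powers >= 2 are
            # excluded (the cos^2 route spans the same functions)
            if any(combo.count(("sin", v)) >= 2 for v in spec.trig_states):
                continue
            trig_sets.append(tuple(sorted(combo)))

    deriv_sets: list[tuple[tuple[str, int], ...]] = [()]
    for d in range(1, spec.derivative_multiplicity + 1):
        for combo in itertools.combinations_with_replacement(
                spec.derivative_names, d):
            exps: dict[str, int] = {}
            for v in combo:
                exps[v] = exps.get(v, 0) + 1
            deriv_sets.append(tuple(sorted(exps.items())))

    seen: set[tuple] = set()
    terms: list[TermDescriptor] = []
    cofactor_cap = spec.deriv_cofactor_degree
    for mono in poly:
        for trig in trig_sets:
            for deriv in deriv_sets:
                if deriv and cofactor_cap is not None and \
                        sum(e for _, e in mono) > cofactor_cap:
                    continue
                exps = dict(mono)
                for v, e in deriv:
                    exps[v] = exps.get(v, 0) + e
                term = TermDescriptor(tuple(exps.items()), trig)
                key = (term.factors, term.trig)
                if key in seen:
                    continue
                seen.add(key)
                terms.append(term)
    if not spec.include_constant:
        terms = [t for t in terms if t.degree > 0]
    terms.sort(key=_term_sort_key)
    labels = [t.label for t in terms]
    if len(set(labels)) != len(labels):  # pragma: no cover - defensive
        raise LibraryError("duplicate term labels in enumeration")
    return terms


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class LibraryMatrix:
    """Evaluated library Theta: an m x p matrix with symbolic column labels."""

    values: np.ndarray
    terms: list[TermDescriptor]
    norms: np.ndarray | None = None
    zero_columns: np.ndarray | None = None
    source: TimeSeriesData | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.terms):
            raise LibraryError("values shape does not match term count")
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise LibraryError("duplicate term labels")

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    @property
    def p(self) -> int:
        return len(self.terms)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise LibraryError(f"no column labelled {label!r}") from None


def evaluate_terms(terms, data: TimeSeriesData) -> LibraryMatrix:
    """Evaluate candidate terms on trajectory data, column by column."""
    m = data.n_samples

    def resolve(name):
        if name is None:
            return np.zeros(m)
        return data.channel(name)

    cols = [t.evaluate(resolve) for t in terms]
    return LibraryMatrix(np.column_stack(cols) if cols else np.empty((m, 0)),
                         list(terms), source=data)


def split_candidate(lib: LibraryMatrix, j: int):
    """Remove column j: returns (lhs term, lhs values, reduced library)."""
    if not 0 <= j < lib.p:
        raise IndexError(f"candidate index {j} out of range for p={lib.p}")
    keep = [i for i in range(lib.p) if i != j]
    reduced = LibraryMatrix(lib.values[:, keep],
                            [lib.terms[i] for i in keep], source=lib.source)
    return lib.terms[j], lib.values[:, j].copy(), reduced


def normalize_columns(lib: LibraryMatrix) -> LibraryMatrix:
    """Scale nonzero columns to unit Euclidean norm, recording the norms.

    Zero columns are flagged (norm recorded as 0) and left untouched so the
    solvers can exclude them; coefficients on normalized columns map back via
    ``xi_original = xi_normalized / norm``.
    """
    norms = np.linalg.norm(lib.values, axis=0)
    zero = norms == 0.0
    scaled = lib.values.copy()
    nz = ~zero
    scaled[:, nz] = scaled[:, nz] / norms[nz]
    return LibraryMatrix(scaled, list(lib.terms), norms=norms,
                         zero_columns=zero, source=lib.source)
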