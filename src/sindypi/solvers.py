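"""Sparse regression solvers.

Three workhorses: sequentially thresholded least squares (STLSQ) for the
per-candidate regressions, a constrained joint solve that reconstructs every
library column from the others under a zero-diagonal constraint, and the
null-space/ADM route used by implicit-SINDy, kept as the noise-fragility
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .library import LibraryMatrix, split_candidate

__all__ = ["SolverConfig", "SparseFit", "stlsq", "constrained_joint_solve",
           "adm_implicit_sindy", "NoNullSpaceError"]


class NoNullSpaceError(RuntimeError):
    """The singular-value cutoff admits no null-space direction.

    This is the known failure mode of the null-space formulation on noisy
    data: measurement noise lifts the smallest singular values above any
    fixed cutoff, so no sparse implicit relation can be extracted.
    """


@dataclass
class SolverConfig:
    """Shared solver settings.

    threshold : hard threshold lambda of STLSQ (applied to coefficients on
        whatever scale the regressors are given, typically unit-norm columns).
    max_iter : STLSQ iteration cap.
    ridge : Tikhonov stabilizer epsilon_r, scaled by trace(A'A)/p; 0 disables.
    nullspace_cutoff : relative singular-value cutoff defining the numerical
        null space for the ADM baseline.
    adm_restarts : seeded random initializations for ADM.
    adm_prune : relative magnitude below which ADM entries count as zero.
    """

    threshold: float = 0.1
    max_iter: int = 25
    ridge: float = 1e-10
    nullspace_cutoff: float = 1e-8
    adm_restarts: int = 10
    adm_max_iter: int = 200
    adm_prune: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


@dataclass
class SparseFit:
    """Result of one sparse regression."""

    coefficients: np.ndarray
    support: np.ndarray
    residual: float
    iterations: int
    converged: bool
    empty: bool = False

    @property
    def sparsity(self) -> int:
        return int(np.count_nonzero(self.support))


def _lstsq(A: np.ndarray, b: np.ndarray, ridge: float) -> np.ndarray:
    if ridge > 0 and A.shape[1] > 0:
        AtA = A.T @ A
        eps = ridge * np.trace(AtA) / max(A.shape[1], 1)
        try:
            return np.linalg.solve(AtA + eps * np.eye(A.shape[1]), A.T @ b)
        except np.linalg.LinAlgError:  # pragma: no cover - fallback
            pass
    return np.linalg.lstsq(A, b, rcond=None)[0]


def stlsq(A: np.ndarray, b: np.ndarray, config: SolverConfig) -> SparseFit:
    """Sequentially thresholded least squares.

    Iterates a least-squares solve on the active set, zeroing out small
    entries below ``config.threshold`` one at a time (smallest first) and
    refitting, until every surviving coefficient clears the threshold.
    The one-at-a-time schedule matters on ill-conditioned libraries: after
    a redundant column is removed the refit re-concentrates weight on the
    remaining columns, whereas zeroing a whole coefficient cluster at once
    can discard genuine terms that shared weight with it.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if A.ndim != 2 or A.shape[0] != b.shape[0]:
        raise ValueError("regressor/target shapes disagree")
    p = A.shape[1]
    if p == 0:
        raise ValueError("empty regressor matrix")
    lam = config.threshold

    # Gram form: subset refits are O(k^3) independent of sample count
    AtA = A.T @ A
    Atb = A.T @ b
    eps = config.ridge * np.trace(AtA) / max(p, 1)

    def solve(mask):
        k = int(mask.sum())
        G = AtA[np.ix_(mask, mask)] + eps * np.eye(k)
        try:
            return np.linalg.solve(G, Atb[mask])
        except np.linalg.LinAlgError:  # pragma: no cover - fallback
            return np.linalg.lstsq(G, Atb[mask], rcond=None)[0]

    support = np.ones(p, dtype=bool)
    xi = np.zeros(p)
    xi[support] = solve(support)
    iterations = 1
    converged = False
    for _ in range(max(config.max_iter * p, p + 1)):
        idx = np.flatnonzero(support)
        small = idx[np.abs(xi[idx]) < lam]
        if small.size == 0:
            converged = True
            break
        drop = small[np.argmin(np.abs(xi[small]))]
        support[drop] = False
        iterations += 1
        if not support.any():
            break
        xi = np.zeros(p)
        xi[support] = solve(support)
    if not support.any():
        resid = float(np.linalg.norm(b))
        return SparseFit(np.zeros(p), support, resid, iterations,
                         converged=True, empty=True)
    # final coefficients: plain least squares on the final support (the
    # ridge stabilizer only steers the thresholding path)
    xi = np.zeros(p)
    xi[support] = np.linalg.lstsq(A[:, support], b, rcond=None)[0]
    resid = float(np.linalg.norm(b - A @ xi))
    return SparseFit(xi, support, resid, iterations, converged)


def constrained_joint_solve(lib: LibraryMatrix,
                            config: SolverConfig) -> np.ndarray:
    """Reconstruct each library column sparsely from the others.

    Solves the joint zero-diagonal problem Theta = Theta * Xi, diag(Xi) = 0,
    by p independent STLSQ fits with column j removed -- algebraically
    equivalent to the constrained formulation because the loss decouples
    column-wise once the diagonal is pinned at zero.
    """
    p = lib.p
    if p < 2:
        raise ValueError("joint solve needs at least 2 columns")
    Xi = np.zeros((p, p))
    for j in range(p):
        _, target, reduced = split_candidate(lib, j)
        fit = stlsq(reduced.values, target, config)
        Xi[np.arange(p) != j, j] = fit.coefficients
    assert np.all(np.diag(Xi) == 0.0)
    return Xi


# ---------------------------------------------------------------------------
# implicit-SINDy baseline: sparsest vector in the numerical null space
# ---------------------------------------------------------------------------

def _nullspace_basis(values: np.ndarray, cutoff: float):
    _, s, vt = np.linalg.svd(values, full_matrices=True)
    p = values.shape[1]
    smax = s[0] if s.size else 0.0
    rank = int(np.sum(s > cutoff * smax))
    dim = p - rank
    if dim <= 0:
        raise NoNullSpaceError(
            "no numerical null space at the configured cutoff")
    return vt[rank:].T, dim


def _sign_convention(v: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(v) > 1e-12 * np.max(np.abs(v)))
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def _support_direction(scaled: np.ndarray, mask: np.ndarray):
    """Best null direction restricted to a support: smallest right singular
    vector of the column submatrix; returns (unit vector on support, s_min)."""
    sub = scaled[:, mask]
    _, s, vt = np.linalg.svd(sub, full_matrices=False)
    v = vt[-1]
    xi = np.zeros(scaled.shape[1])
    xi[mask] = v
    return xi, float(s[-1])


def adm_implicit_sindy(lib: LibraryMatrix, config: SolverConfig) -> SparseFit:
    """Sparsest unit-norm vector in the numerical null space of Theta.

    The alternating-directions iteration soft-thresholds the candidate
    vector and projects back onto the null-space basis; restarts are
    seeded.  Converged iterates are pruned at the configured relative
    tolerance, refit on their support, and the sparsest vector whose
    residual is close to the best achieved wins.
    """
    if lib.p < 2:
        raise ValueError("need at least 2 library columns")
    values = lib.values
    scale = np.linalg.norm(values, axis=0)
    scale[scale == 0] = 1.0
    scaled = values / scale
    basis, dim = _nullspace_basis(scaled, config.nullspace_cutoff)
    smax = float(np.linalg.norm(scaled, 2))

    rng = np.random.default_rng(config.seed)
    p = lib.p
    candidates = []
    lambdas = np.geomspace(1e-3, 0.5, 8)
    inits = [basis[:, k] for k in range(dim)]
    inits += [basis @ rng.standard_normal(dim)
              for _ in range(config.adm_restarts)]
    seen: set[tuple] = set()
    for lam in lambdas:
        for q0 in inits:
            nrm = np.linalg.norm(q0)
            if nrm == 0:
                continue
            x = q0 / nrm
            for _ in range(config.adm_max_iter):
                soft = np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)
                q = basis.T @ soft
                nq = np.linalg.norm(q)
                if nq == 0:
                    break
                x_new = basis @ (q / nq)
                if np.linalg.norm(x_new - x) < 1e-10:
                    x = x_new
                    break
                x = x_new
            mask = np.abs(x) >= config.adm_prune * np.max(np.abs(x))
            if not mask.any():
                continue
            key0 = tuple(np.flatnonzero(mask))
            if key0 in seen:
                continue
            seen.add(key0)
            xi, resid = _support_direction(scaled, mask)
            candidates.append((mask, xi, resid))
    if not candidates:
        raise NoNullSpaceError("ADM failed to produce any candidate vector")
    # sparsest vector whose fit is close to the best achieved
    r_best = min(c[2] for c in candidates)
    viable = [c for c in candidates if c[2] <= 3.0 * r_best + 1e-12 * smax]
    mask, xi, _ = min(viable, key=lambda c: (int(c[0].sum()), c[2]))
    # undo the column scaling: relation holds for original columns
    xi = xi / scale
    xi /= np.linalg.norm(xi)
    xi = _sign_convention(xi)
    resid = float(np.linalg.norm(values @ xi))
    return SparseFit(xi, np.abs(xi) > 0, resid, iterations=config.adm_max_iter,
                     converged=True)
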