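"""Exploratory factor analysis: minres extraction and oblique rotation.

Extraction is ordinary minres/ULS: for fixed uniquenesses the loadings
are the scaled top-k eigenvectors of R - diag(psi), and psi is chosen to
minimise the sum of squared residual eigenvalues.  Rotation uses the
gradient-projection algorithm of Jennrich for two oblique criteria:

* direct oblimin with gamma = 0 (direct quartimin), and
* partially specified target rotation, which only penalises loadings at
  positions the target declares to be zero.

Iterated target rotation (ITR) alternates target rotation with
rebuilding the zero pattern from the current solution (|loading| below
the cutoff -> specified zero) until the pattern stabilises.  Unlike a
one-shot simple-structure rotation, ITR can recover genuine
cross-loadings because positions above the cutoff are left free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .correlation import CorrelationMatrix

_SIGN_EPS = 1e-8


@dataclass
class UnrotatedLoadings:
    loadings: np.ndarray  # items x k
    communalities: np.ndarray
    residual: float  # minres objective at optimum
    heywood: list[int] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass
class RotatedSolution:
    loadings: np.ndarray  # pattern matrix, items x k
    phi: np.ndarray  # k x k factor correlations
    rotation: str  # "oblimin" | "target"
    iterations: int = 1
    converged: bool = True

    def implied(self) -> np.ndarray:
        """Model-implied common part Lambda Phi Lambda' (rotation invariant)."""
        return self.loadings @ self.phi @ self.loadings.T


@dataclass
class TargetMatrix:
    """Zero-pattern target: weight 1 where a loading is pinned to zero."""

    weights: np.ndarray  # 1 = specified zero, 0 = free

    @classmethod
    def from_loadings(cls, loadings: np.ndarray, cutoff: float) -> "TargetMatrix":
        return cls((np.abs(loadings) < cutoff).astype(float))

    def pattern_key(self) -> bytes:
        return np.packbits(self.weights.astype(bool)).tobytes()


def _canonicalize(L: np.ndarray, phi: np.ndarray | None = None):
    """Order columns by decreasing sum of squares; first nonzero entry >= 0."""
    order = np.argsort(-np.sum(L * L, axis=0), kind="stable")
    L = L[:, order]
    if phi is not None:
        phi = phi[np.ix_(order, order)]
    signs = np.ones(L.shape[1])
    for j in range(L.shape[1]):
        col = L[:, j]
        nz = np.nonzero(np.abs(col) > _SIGN_EPS)[0]
        if nz.size and col[nz[0]] < 0:
            signs[j] = -1.0
    L = L * signs
    if phi is not None:
        phi = phi * np.outer(signs, signs)
        np.fill_diagonal(phi, 1.0)
    return (L, phi) if phi is not None else (L, None)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _minres_objective(psi: np.ndarray, R: np.ndarray, k: int):
    S = R - np.diag(psi)
    w, v = np.linalg.eigh(S)
    # residual = sum of squared eigenvalues beyond the k retained
    tail = w[:-k] if k else w
    f = float(np.sum(tail**2))
    grad = -2.0 * (v[:, :-k] ** 2) @ tail if k else None
    return f, grad, w, v


def extract_minres(R: CorrelationMatrix | np.ndarray, k: int) -> UnrotatedLoadings:
    """Minimum-residual (ULS) factor extraction.

    Minimises the sum of squared off-diagonal residuals of R - LL'.
    Communalities above 0.995 (Heywood cases) are capped with a warning.
    """
    Rm = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, float)
    p = Rm.shape[0]
    if not 1 <= k < p:
        raise ValueError(f"k must be in [1, {p - 1}]")

    from scipy.optimize import minimize

    psi0 = np.maximum(1.0 / np.maximum(np.diag(np.linalg.pinv(Rm)), 1.0), 0.05)
    bounds = [(0.005, 1.0)] * p

    def fg(psi):
        f, grad, _, _ = _minres_objective(psi, Rm, k)
        return f, grad

    res = minimize(fg, psi0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10})
    psi = res.x
    _, _, w, v = _minres_objective(psi, Rm, k)
    top_w = np.maximum(w[-k:][::-1], 0.0)
    top_v = v[:, -k:][:, ::-1]
    L = top_v * np.sqrt(top_w)

    heywood = [int(i) for i in np.nonzero(psi <= 0.005 + 1e-9)[0]]
    if heywood:
        warnings.warn(
            f"Heywood case: communality capped at 0.995 for items {heywood}",
            stacklevel=2,
        )
    L, _ = _canonicalize(L)
    h2 = np.sum(L * L, axis=1)
    return UnrotatedLoadings(L, h2, residual=float(res.fun), heywood=heywood)


# ---------------------------------------------------------------------------
# rotation criteria + gradient projection
# ---------------------------------------------------------------------------

def _vgq_quartimin(L: np.ndarray):
    L2 = L * L
    N = np.ones((L.shape[1],) * 2) - np.eye(L.shape[1])
    X = L2 @ N
    f = float(np.sum(L2 * X)) / 4.0
    Gq = L * X
    return f, Gq


def _vgq_target(L: np.ndarray, weights: np.ndarray):
    D = weights * L  # target values are zero at specified positions
    f = float(np.sum(D * D))
    Gq = 2.0 * D
    return f, Gq


def _gpa_oblique(A: np.ndarray, vgq, T0: np.ndarray | None = None,
                 max_iter: int = 1000, tol: float = 1e-6):
    """Gradient-projection oblique rotation (Jennrich 2002).

    Returns (pattern L, phi, criterion value, iterations, converged).
    """
    k = A.shape[1]
    T = np.eye(k) if T0 is None else T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = vgq(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        Gp = G - T * np.sum(T * G, axis=0, keepdims=True)
        s = float(np.sqrt(np.sum(Gp * Gp)))
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            X = X / np.sqrt(np.sum(X * X, axis=0, keepdims=True))
            Xi = np.linalg.inv(X)
            Lt = A @ Xi.T
            ft, Gqt = vgq(Lt)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T, Ti, L, f, Gq = X, Xi, Lt, ft, Gqt
        G = -(L.T @ Gq @ Ti).T
    phi = T.T @ T
    return L, phi, f, it, converged


def rotate_oblimin(unrotated: UnrotatedLoadings) -> RotatedSolution:
    """Direct oblimin (gamma = 0, i.e. direct quartimin) rotation."""
    if unrotated.k < 2:
        raise ValueError("rotation needs k >= 2")
    L, phi, _, it, conv = _gpa_oblique(unrotated.loadings, _vgq_quartimin)
    if not conv:
        raise RuntimeError(
            f"oblimin rotation did not converge in {it} iterations"
        )
    L, phi = _canonicalize(L, phi)
    return RotatedSolution(L, phi, "oblimin", iterations=it, converged=conv)


def rotate_target(unrotated: UnrotatedLoadings, target: TargetMatrix
                  ) -> tuple[RotatedSolution, float]:
    """Oblique rotation to a partially specified (zero-pattern) target."""
    L, phi, f, it, conv = _gpa_oblique(
        unrotated.loadings, lambda M: _vgq_target(M, target.weights)
    )
    return RotatedSolution(L, phi, "target", iterations=it, converged=conv), f


def iterated_target_rotation(
    unrotated: UnrotatedLoadings,
    cutoff: float = 0.30,
    max_iter: int = 25,
) -> RotatedSolution:
    """ITR: alternate target rotation and target rebuilding to a fixed point.

    The initial target zero-pattern comes from the oblimin solution; the
    loop stops when the pattern repeats (fixed point) or ``max_iter`` is
    reached.  A detected cycle returns the member with the lowest target
    criterion, with a warning.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    if unrotated.k < 2:
        raise ValueError("ITR needs k >= 2")

    sol = rotate_oblimin(unrotated)
    target = TargetMatrix.from_loadings(sol.loadings, cutoff)
    seen: dict[bytes, int] = {target.pattern_key(): 0}
    history: list[tuple[RotatedSolution, float]] = []

    for it in range(1, max_iter + 1):
        sol, f = rotate_target(unrotated, target)
        # evaluate the *rebuilt* pattern against the canonical solution so
        # the fixed-point test is invariant to column order/sign
        new_target = TargetMatrix.from_loadings(sol.loadings, cutoff)
        history.append((sol, f))
        key = new_target.pattern_key()
        if key == target.pattern_key():
            sol.iterations = it
            return _canonical_solution(sol)
        if key in seen:
            warnings.warn(
                "ITR pattern cycle detected; returning lowest-criterion member",
                stacklevel=2,
            )
            best, _ = min(history, key=lambda t: t[1])
            best.iterations = it
            best.converged = False
            return _canonical_solution(best)
        seen[key] = it
        target = new_target

    warnings.warn(f"ITR did not stabilise within {max_iter} iterations",
                  stacklevel=2)
    sol.iterations = max_iter
    sol.converged = False
    return _canonical_solution(sol)


def _canonical_solution(sol: RotatedSolution) -> RotatedSolution:
    L, phi = _canonicalize(sol.loadings, sol.phi)
    return RotatedSolution(L, phi, sol.rotation, sol.iterations, sol.converged)


# ---------------------------------------------------------------------------
# factor retention
# ---------------------------------------------------------------------------

def retain_factors(
    R: CorrelationMatrix | np.ndarray,
    n_subjects: int,
    n_resamples: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Horn's parallel analysis: k = #(eigenvalues above resampled quantile).

    Returns (k, observed eigenvalues, threshold eigenvalues).  Raises if
    no eigenvalue clears its threshold (no common variance).
    """
    Rm = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R, float)
    p = Rm.shape[0]
    obs = np.sort(np.linalg.eigvalsh(Rm))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_resamples, p))
    for b in range(n_resamples):
        X = rng.standard_normal((n_subjects, p))
        sims[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    thresh = np.percentile(sims, percentile, axis=0)
    above = obs > thresh
    k = int(np.argmin(above)) if not above.all() else p
    if k == 0:
        raise ValueError(
            "parallel analysis retains 0 factors; inspect the panel"
        )
    return k, obs, thresh
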