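"""Mean-field free-energy landscape and asymptotic pair-correlation theory.

The de Finetti representation expresses every model expectation as a ratio
of integrals of ``exp(-N F)`` where

    F(x) = 1/2 x^T J^{-1} x - sum_l alpha_l ln cosh(x_l / sqrt(alpha_l)),

so the minima of ``F`` govern the large-N behaviour.  The ``sqrt(alpha_l)``
argument scaling is the unique convention under which the Hessian of ``F``
at the origin equals ``H = J^{-1} - I``; see docs/methods.md.

High temperature (``I - J > 0``): the origin is the unique minimum and a
Laplace expansion gives, for individuals ``i`` in group ``l`` and ``j`` in
group ``m`` (``i != j``),

    E(X_i X_j) ~ H^{-1}_{lm} / (sqrt(alpha_l alpha_m) N).

The ``1/sqrt(alpha_l alpha_m)`` factor is required for consistency with
the exactly solvable block-diagonal case (independent groups reduce to
single-group Curie-Weiss models of size ``alpha_l N``); the scaled matrix
``L = D^{-1} H^{-1} D^{-1}`` with ``D = diag(sqrt(alpha_l))`` is called the
*level matrix* here, since ``L_{lm}/N`` are the correlation levels the
detection windows are built around.

Low temperature (non-critical): ``F`` has finitely many global minima
``z^(k)`` with positive-definite Hessians ``H_k``, and

    E(X_i X_j) -> <Z_l, Z_m>,
    Z_l[k] = det(H_k)^{-1/4} tanh(z^(k)_l / sqrt(alpha_l)) / sqrt(sum_j det(H_j)^{-1/2}).

Detection is possible only when the ``Z_l`` are pairwise distinct; the
separation constants ``delta`` (high) and ``gamma`` (low) quantify the
worst-case gap between correlation levels and enter the exponential
failure-probability bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import (
    BlockSpinModel,
    BlockSpinError,
    CriticalRegimeError,
    NonIdentifiableError,
)

__all__ = [
    "free_energy",
    "free_energy_derivatives",
    "Minimum",
    "Landscape",
    "find_minima",
    "HighTempTheory",
    "pair_limit_high",
    "z_vectors",
    "SeparationConstants",
    "separation_constants",
    "separation_from_matrix",
    "failure_bound",
    "min_observations",
]


def free_energy(model: BlockSpinModel, x) -> float:
    """Evaluate ``F`` at a point of R^M.  ``F(0) = 0`` and ``F`` is even."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.M,):
        raise BlockSpinError(f"point must have dimension M={model.M}")
    a = model.alphas
    Jinv = np.linalg.inv(model.J)
    return float(0.5 * x @ Jinv @ x - np.sum(a * np.log(np.cosh(x / np.sqrt(a)))))


def free_energy_derivatives(model: BlockSpinModel, x):
    """Analytic gradient and Hessian of ``F``.

    grad_l = (J^{-1} x)_l - sqrt(alpha_l) tanh(x_l / sqrt(alpha_l))
    Hess   = (J^{-1} - I) + diag(tanh^2(x_l / sqrt(alpha_l)))

    At the origin the Hessian equals ``H = J^{-1} - I`` exactly.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.M,):
        raise BlockSpinError(f"point must have dimension M={model.M}")
    a = model.alphas
    Jinv = np.linalg.inv(model.J)
    t = np.tanh(x / np.sqrt(a))
    grad = Jinv @ x - np.sqrt(a) * t
    hess = (Jinv - np.eye(model.M)) + np.diag(t**2)
    return grad, hess


@dataclass(frozen=True)
class Minimum:
    """A verified global minimum of ``F``: location, Hessian, determinant, value."""

    z: np.ndarray
    hessian: np.ndarray
    det: float
    fval: float


@dataclass(frozen=True)
class Landscape:
    """Global minima of ``F`` plus the derived Z-vectors and their Gram matrix.

    ``Z`` has shape ``(M, K)`` (row ``l`` is the vector of group ``l``);
    ``gram[l, m] = <Z_l, Z_m>`` is the low-temperature limiting correlation
    between groups ``l`` and ``m``.  ``identifiable`` is False when two
    groups share the same Z-vector (Gram rows coincide), in which case
    low-temperature detection refuses to run.
    """

    minima: tuple
    alpha_min: float
    Z: np.ndarray = field(default=None)  # type: ignore[assignment]
    gram: np.ndarray = field(default=None)  # type: ignore[assignment]
    identifiable: bool = field(default=None)  # type: ignore[assignment]

    @property
    def K(self) -> int:
        return len(self.minima)


def _newton_polish(model, x, max_iter=50, gtol=1e-11):
    """Drive the gradient norm below ``gtol`` with damped Newton steps."""
    x = np.array(x, dtype=float)
    for _ in range(max_iter):
        g, h = free_energy_derivatives(model, x)
        if np.linalg.norm(g) <= gtol:
            break
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            break
        x -= step
    return x


def find_minima(
    model: BlockSpinModel,
    n_random_starts: int = 50,
    seed: int = 0,
    dedup_tol: float = 1e-5,
    f_tol: float = 1e-9,
    grad_tol: float = 1e-8,
) -> Landscape:
    """Locate all global minima of ``F`` by polished multi-start quasi-Newton.

    Starts are every sign pattern in {-1, 0, +1}^M scaled componentwise by
    ``2 sqrt(alpha)`` plus ``n_random_starts`` uniform draws from the box
    ``[-R, R]^M`` with ``R = 2 lambda_max(J)`` (outside which ``F > F(0)``
    by the quadratic-growth bound).  Candidates are polished with Newton
    steps, deduplicated at ``dedup_tol`` in the infinity norm, and filtered
    to ``fval`` within ``f_tol`` of the best.  Every returned minimum is
    verified: gradient norm <= ``grad_tol`` and positive-definite Hessian
    (otherwise a :class:`CriticalRegimeError` is raised).  The returned set
    is closed under the sign flip ``z -> -z``.
    """
    M = model.M
    Jinv = np.linalg.inv(model.J)

    def fun(x):
        return free_energy(model, x)

    def jac(x):
        return free_energy_derivatives(model, x)[0]

    R = 2.0 * np.linalg.eigvalsh(model.J).max()
    rng = np.random.default_rng(seed)
    starts = []
    base = 2.0 * np.sqrt(model.alphas)
    grids = np.meshgrid(*([np.array([-1.0, 0.0, 1.0])] * M), indexing="ij")
    for sigma in np.stack([g.ravel() for g in grids], axis=1):
        starts.append(sigma * base)
    starts.extend(rng.uniform(-R, R, size=(n_random_starts, M)))

    candidates = []
    for x0 in starts:
        res = minimize(fun, x0, jac=jac, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
        candidates.append(_newton_polish(model, res.x))
    # closure under sign flip before dedup (F is even)
    candidates.extend([-c for c in candidates])

    unique: list[np.ndarray] = []
    for c in candidates:
        if not any(np.max(np.abs(c - u)) <= dedup_tol for u in unique):
            unique.append(c)

    fvals = np.array([fun(u) for u in unique])
    best = fvals.min()
    minima = []
    for u, fv in zip(unique, fvals):
        if fv - best > f_tol:
            continue
        g, h = free_energy_derivatives(model, u)
        gnorm = float(np.linalg.norm(g))
        if gnorm > grad_tol:
            raise BlockSpinError(
                f"optimizer failed to converge at {u} (|grad|={gnorm:.2e})"
            )
        eigs = np.linalg.eigvalsh(h)
        if eigs.min() <= 1e-10 * max(1.0, np.abs(eigs).max()):
            raise CriticalRegimeError(
                "critical landscape: Hessian at a minimum is not positive definite"
            )
        minima.append(Minimum(z=u, hessian=h, det=float(np.linalg.det(h)), fval=float(fv)))

    # deterministic ordering (lexicographic by coordinates)
    minima.sort(key=lambda m: tuple(np.round(m.z, 10)))
    landscape = Landscape(minima=tuple(minima), alpha_min=float(best))
    return z_vectors(model, landscape)


def z_vectors(model: BlockSpinModel, landscape: Landscape) -> Landscape:
    """Fill in the Z-vectors and their Gram matrix.

    ``Z_l[k] = det(H_k)^{-1/4} tanh(z^(k)_l / sqrt(alpha_l)) / sqrt(sum_j det(H_j)^{-1/2})``

    so that ``gram = Z Z^T`` reproduces the leading Laplace ratio

    ``gram_{lm} = sum_k det(H_k)^{-1/2} t_l^k t_m^k / sum_k det(H_k)^{-1/2}``,

    ``t_l^k = tanh(z^(k)_l / sqrt(alpha_l))``.
    """
    a = model.alphas
    dets = np.array([m.det for m in landscape.minima])
    T = np.stack([np.tanh(m.z / np.sqrt(a)) for m in landscape.minima], axis=1)  # M x K
    w = dets**-0.25 / math.sqrt(float(np.sum(dets**-0.5)))
    Z = T * w[None, :]
    gram = Z @ Z.T
    identifiable = True
    for l in range(model.M):
        for m in range(l + 1, model.M):
            if np.linalg.norm(Z[l] - Z[m]) <= 1e-8 * max(1.0, np.abs(Z).max()):
                identifiable = False
    return Landscape(
        minima=landscape.minima,
        alpha_min=landscape.alpha_min,
        Z=Z,
        gram=gram,
        identifiable=identifiable,
    )


@dataclass(frozen=True)
class HighTempTheory:
    """High-temperature asymptotic pair-correlation theory.

    ``H = J^{-1} - I``; ``level_matrix = D^{-1} H^{-1} D^{-1}`` with
    ``D = diag(sqrt(alpha_l))``, so the limiting pair correlation of groups
    ``(l, m)`` is ``level_matrix[l, m] / N``.
    """

    H: np.ndarray
    H_inv: np.ndarray
    level_matrix: np.ndarray
    alphas: np.ndarray

    def pair_limit(self, N: int) -> np.ndarray:
        """Per-group-pair limiting correlations at population size ``N``."""
        return self.level_matrix / N


def pair_limit_high(model: BlockSpinModel) -> HighTempTheory:
    """Asymptotic pair-correlation theory; requires the high-temperature regime."""
    reg = model.regime()
    if reg.tag != "high":
        raise CriticalRegimeError(f"regime is '{reg.tag}', not high temperature")
    H = np.linalg.inv(model.J) - np.eye(model.M)
    H_inv = np.linalg.inv(H)
    d = np.sqrt(model.alphas)
    level = H_inv / np.outer(d, d)
    return HighTempTheory(H=H, H_inv=H_inv, level_matrix=level, alphas=model.alphas)


@dataclass(frozen=True)
class SeparationConstants:
    """Minimal gaps between limiting correlation levels (eta, xi, and their min)."""

    eta: float
    xi: float
    value: float
    regime: str


def separation_from_matrix(A, regime: str = "high", eq_tol: float | None = None) -> SeparationConstants:
    """Separation constants from a symmetric matrix of limiting correlations.

    High temperature (matrix ``A`` plays the role of ``H^{-1}`` or of the
    alpha-scaled level matrix):

        eta = min_{l != m} max{A_ll, A_mm} - A_lm          (all pairs)
        xi  = min_{l != m, A_ll != A_mm} |A_ll - A_mm|     (+inf if empty)

    Low temperature (``A`` is the Gram matrix of the Z-vectors):

        eta = min over pairs with different diagonals of |A_ll - A_mm|
        xi  = min over pairs with equal diagonals of |A_ll - A_lm|

    Diagonal entries are considered equal when they differ by at most
    ``eq_tol`` (default ``1e-9 * max|diag|``).  ``M = 1`` returns +inf
    (a single group needs no separation).  A nonpositive result raises
    :class:`NonIdentifiableError`.
    """
    A = np.asarray(A, dtype=float)
    M = A.shape[0]
    if M == 1:
        return SeparationConstants(eta=math.inf, xi=math.inf, value=math.inf, regime=regime)
    d = np.diag(A)
    if eq_tol is None:
        eq_tol = 1e-9 * max(np.abs(d).max(), 1e-300)

    eta_vals, xi_vals = [], []
    for l in range(M):
        for m in range(l + 1, M):
            diag_gap = abs(d[l] - d[m])
            if regime == "high":
                eta_vals.append(max(d[l], d[m]) - A[l, m])
                if diag_gap > eq_tol:
                    xi_vals.append(diag_gap)
            else:
                if diag_gap > eq_tol:
                    eta_vals.append(diag_gap)
                else:
                    xi_vals.append(abs(d[l] - A[l, m]))
    eta = min(eta_vals) if eta_vals else math.inf
    xi = min(xi_vals) if xi_vals else math.inf
    value = min(eta, xi)
    if not value > eq_tol:
        raise NonIdentifiableError(
            f"separation constant is {value:.3e}: two groups share a correlation "
            "level and cannot be distinguished (identifiability assumption violated)"
        )
    return SeparationConstants(eta=float(eta), xi=float(xi), value=float(value), regime=regime)


def separation_constants(theory) -> SeparationConstants:
    """Dispatch on :class:`HighTempTheory` (delta) or :class:`Landscape` (gamma)."""
    if isinstance(theory, HighTempTheory):
        return separation_from_matrix(theory.level_matrix, regime="high")
    if isinstance(theory, Landscape):
        if theory.gram is None:
            raise BlockSpinError("landscape has no Z-vectors; run find_minima first")
        if not theory.identifiable:
            raise NonIdentifiableError(
                "two groups have identical Z-vectors; the model is not identifiable"
            )
        return separation_from_matrix(theory.gram, regime="low")
    raise TypeError(f"unsupported theory object {type(theory)!r}")


def _log_failure_bound(regime: str, N: int, n: int, sep: float) -> float:
    if sep == math.inf:
        return -math.inf
    arg = sep / (8.0 * N) if regime == "high" else sep / 8.0
    return 2.0 * math.log(N) + 2.0 * math.log(n + 1.0) - 0.125 * arg * arg * n


def failure_bound(regime: str, N: int, n: int, sep) -> float:
    """Upper bound on the probability that exact recovery fails.

    ``e_high(n) = N^2 (n+1)^2 exp(-(1/8) (delta/(8N))^2 n)`` and
    ``e_low(n) = N^2 (n+1)^2 exp(-(1/8) (gamma/8)^2 n)``.  The bound may
    exceed 1 (vacuous) for small ``n``.
    """
    if regime not in ("high", "low"):
        raise BlockSpinError("regime must be 'high' or 'low'")
    if n < 0:
        raise BlockSpinError("n must be >= 0")
    value = sep.value if isinstance(sep, SeparationConstants) else float(sep)
    logb = _log_failure_bound(regime, N, n, value)
    return math.exp(min(logb, 700.0))


def min_observations(regime: str, N: int, sep, eps: float, n_max: int = 10**15) -> int:
    """Smallest ``n`` with ``failure_bound(n) <= eps``.

    The bound increases up to its turning point and decreases thereafter;
    the search bisects in the decreasing branch, so the returned ``n*``
    satisfies ``bound(n*) <= eps < bound(n* - 1)``.  This is a *sufficient*
    and typically very conservative sample size.
    """
    if not 0 < eps < 1:
        raise BlockSpinError("eps must be in (0, 1)")
    value = sep.value if isinstance(sep, SeparationConstants) else float(sep)
    if value == math.inf:
        return 1
    log_eps = math.log(eps)

    def logb(n: int) -> float:
        return _log_failure_bound(regime, N, n, value)

    arg = value / (8.0 * N) if regime == "high" else value / 8.0
    c = 0.125 * arg * arg
    turning = max(1, int(2.0 / c))
    hi = turning
    while logb(hi) > log_eps:
        hi *= 2
        if hi > n_max:
            raise BlockSpinError(f"required n exceeds {n_max:g}")
    lo = 1
    while lo < hi:
        mid = (lo + hi) // 2
        # monotone decrease only holds beyond the turning point; below it the
        # bound exceeds N^2 >= 4 > eps, so the first crossing is unique
        if mid >= turning and logb(mid) <= log_eps:
            hi = mid
        else:
            lo = mid + 1
    return lo
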