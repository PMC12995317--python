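"""Independent reference computations used for validation.

Three mutually independent routes to the exact pair correlations
``E(X_i X_j)`` exist at small scale and must agree:

1. brute-force summation over all ``2^N`` configurations,
2. averaging the conditional correlation given the group sums over the
   exact sufficient-statistic distribution,
3. the de Finetti integral identity ``E(X_i X_j) = Z_2(N) / Z_0(N)``
   with ``Z_2, Z_0`` integrals of ``exp(-N F)`` (numerical quadrature).

The module also provides the information-theoretic ingredients of the
sample-complexity bounds (relative entropy of two Bernoulli pair laws and
the Sanov-type tail bound) and a seeded batch recovery experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .model import BlockSpinModel, BlockSpinError, DEFAULT_STATE_CAP
from .sampler import group_sum_distribution, draw_sample
from .landscape import free_energy
from .detect import (
    CommunityDetector,
    empirical_correlations,
)

__all__ = [
    "BernoulliPairLaw",
    "enumerate_pair_correlations",
    "sufficient_pair_correlations",
    "definetti_pair_correlation",
    "relative_entropy",
    "sanov_upper_bound",
    "recovery_experiment",
    "RecoverySummary",
]


@dataclass(frozen=True)
class BernoulliPairLaw:
    """Law of a spin product: ``p_minus = P(X_i X_j = -1)``."""

    p_minus: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_minus <= 1.0:
            raise BlockSpinError("p_minus must lie in [0, 1]")

    @property
    def p_plus(self) -> float:
        return 1.0 - self.p_minus

    @property
    def mean(self) -> float:
        return self.p_plus - self.p_minus


def enumerate_pair_correlations(model: BlockSpinModel) -> np.ndarray:
    """Exact ``E(X_i X_j)`` for all pairs by summation over all 2^N configurations.

    Guarded at ``N <= 16``.  The diagonal is set to 1.
    """
    N = model.N
    if N > 16:
        raise BlockSpinError("enumeration is capped at N = 16")
    codes = np.arange(2**N, dtype=np.int64)
    X = (((codes[:, None] >> np.arange(N)[None, :]) & 1) * 2 - 1).astype(np.float64)
    S = np.stack(
        [X[:, model.labels == l].sum(axis=1) for l in range(model.M)], axis=1
    )
    sc = S / np.sqrt(model.sizes)
    logw = 0.5 * np.einsum("kl,lm,km->k", sc, model.J, sc)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    corr = (X * w[:, None]).T @ X
    np.fill_diagonal(corr, 1.0)
    return corr


def sufficient_pair_correlations(
    model: BlockSpinModel, cap: int = DEFAULT_STATE_CAP
) -> np.ndarray:
    """Exact ``E(X_i X_j)`` via the sufficient-statistic distribution.

    Within-group exchangeability gives, conditionally on the group sums,

        E(X_i X_j | s) = (s_l^2 - N_l) / (N_l (N_l - 1))   (i != j, both in l)
        E(X_i X_j | s) = s_l s_m / (N_l N_m)               (i in l, j in m != l)

    so only the second moments ``E[s_l s_m]`` are needed.  Agrees with
    :func:`enumerate_pair_correlations` to machine precision and scales to
    populations in the thousands for small M.
    """
    dist = group_sum_distribution(model, cap=cap)
    Es2 = dist.moment2()
    sizes = model.sizes.astype(float)
    M = model.M
    block = np.empty((M, M))
    for l in range(M):
        for m in range(M):
            if l == m:
                block[l, l] = (Es2[l, l] - sizes[l]) / (sizes[l] * (sizes[l] - 1.0))
            else:
                block[l, m] = Es2[l, m] / (sizes[l] * sizes[m])
    corr = block[np.ix_(model.labels, model.labels)]
    np.fill_diagonal(corr, 1.0)
    return corr


def _quadrature_box(model: BlockSpinModel, N: int, log_threshold: float = 40.0):
    """Box containing all mass of exp(-N (F - F_min)) above exp(-threshold).

    Locates the minimum of F by a coarse grid plus a local polish (no
    Hessian verification, so this also works at critical couplings where
    the landscape module would refuse) and bounds the box through the
    quadratic growth F(x) >= lam/2 ||x||^2 - ||x||, lam = min eig(J^{-1}).
    """
    from scipy.optimize import minimize as _minimize

    lam = float(np.linalg.eigvalsh(np.linalg.inv(model.J)).min())
    R0 = 2.0 / lam + 2.0  # F > 0 = F(0) outside this radius
    grids = np.meshgrid(*([np.linspace(-R0, R0, 41)] * model.M), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    vals = [free_energy(model, p) for p in pts]
    x0 = pts[int(np.argmin(vals))]

    def fun(x):
        return free_energy(model, x)

    res = _minimize(fun, x0, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14})
    fmin = min(float(res.fun), float(np.min(vals)))
    zmax = float(np.abs(res.x).max())
    c = fmin + log_threshold / max(N, 1)
    R = (1.0 + math.sqrt(max(1.0 + 2.0 * lam * c, 0.0))) / lam
    return fmin, max(R, zmax + 3.0)


def definetti_pair_correlation(model: BlockSpinModel, i: int, j: int) -> float:
    """``E(X_i X_j)`` through the de Finetti integral identity.

    ``Z_2 = int exp(-N F(x)) tanh(x_{iota(i)}/sqrt(alpha)) tanh(x_{iota(j)}/sqrt(alpha)) dx``
    and ``Z_0`` the same integral without the tanh factors; the expectation
    is their ratio.  Adaptive quadrature over a box outside which the
    integrand is below ``exp(-40)`` of its peak; guarded at ``M <= 2``.
    """
    if model.M > 2:
        raise BlockSpinError("quadrature oracle is limited to M <= 2")
    if i == j:
        raise BlockSpinError("requires i != j")
    N = model.N
    a = model.alphas
    li, lj = model.labels[i], model.labels[j]
    fmin, R = _quadrature_box(model, N)

    def weight(x):
        return math.exp(-N * (free_energy(model, x) - fmin))

    if model.M == 1:

        def f0(x1):
            return weight(np.array([x1]))

        def f2(x1):
            t = math.tanh(x1 / math.sqrt(a[0]))
            return f0(x1) * t * t

        z0, _ = integrate.quad(f0, -R, R, limit=200)
        z2, _ = integrate.quad(f2, -R, R, limit=200)
    else:

        def f0(x2, x1):
            return weight(np.array([x1, x2]))

        def f2(x2, x1):
            return (
                f0(x2, x1)
                * math.tanh((x1 if li == 0 else x2) / math.sqrt(a[li]))
                * math.tanh((x1 if lj == 0 else x2) / math.sqrt(a[lj]))
            )

        z0, _ = integrate.dblquad(f0, -R, R, -R, R, epsabs=1e-12, epsrel=1e-10)
        z2, _ = integrate.dblquad(f2, -R, R, -R, R, epsabs=1e-12, epsrel=1e-10)
    if z0 <= 0:
        raise BlockSpinError("quadrature failed: nonpositive normalisation")
    return float(z2 / z0)


def relative_entropy(nu: BernoulliPairLaw, theta: BernoulliPairLaw) -> float:
    """``H(nu | theta)`` with the conventions 0 log 0 = 0 and H = +inf when
    absolute continuity fails.  Satisfies ``H >= eps^2 / 8`` whenever the
    means differ by at least ``eps``."""
    total = 0.0
    for p, q in ((nu.p_minus, theta.p_minus), (nu.p_plus, theta.p_plus)):
        if p == 0.0:
            continue
        if q == 0.0:
            return math.inf
        total += p * math.log(p / q)
    return max(total, 0.0)


def sanov_upper_bound(n: int, eps: float) -> float:
    """Tail bound ``(n+1)^2 exp(-n eps^2 / 8)`` for the empirical pair mean."""
    if n < 1:
        raise BlockSpinError("n must be >= 1")
    if not 0 < eps < 1:
        raise BlockSpinError("eps must be in (0, 1)")
    return (n + 1.0) ** 2 * math.exp(-n * eps * eps / 8.0)


@dataclass(frozen=True)
class RecoverySummary:
    """Outcome of a batch recovery experiment."""

    reps: int
    successes: int
    statuses: tuple
    seed: int | None

    @property
    def rate(self) -> float:
        return self.successes / self.reps if self.reps else math.nan


def recovery_experiment(
    model: BlockSpinModel,
    n: int,
    reps: int,
    seed: int,
    regime: str = "auto",
) -> RecoverySummary:
    """Estimate the exact-recovery probability by seeded simulation.

    Each replicate draws ``n`` observations, computes empirical
    correlations, runs the theory-driven detection and compares the
    recovered partition to the planted one *as unlabeled partitions* (the
    guarantee concerns the partition, not the group names).  Replicate
    seeds are spawned from ``seed`` deterministically.
    """
    if reps == 0:
        return RecoverySummary(reps=0, successes=0, statuses=(), seed=seed)
    planted = frozenset(
        frozenset(int(i) for i in np.flatnonzero(model.labels == l))
        for l in range(model.M)
    )
    detector = CommunityDetector(model=model, regime=regime)
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(reps)]
    statuses = []
    successes = 0
    for s in child_seeds:
        sample = draw_sample(model, n, seed=s)
        det = detector.fit(sample.data)
        ok = det.result_.status == "success" and det.result_.as_partition() == planted
        statuses.append(det.result_.status if not ok else "success")
        if ok:
            successes += 1
        elif det.result_.status == "success":
            statuses[-1] = "wrong_partition"
    return RecoverySummary(
        reps=reps, successes=successes, statuses=tuple(statuses), seed=seed
    )
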