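"""Exact and approximate samplers for the block spin Ising model.

The Gibbs measure depends on a configuration only through the group-sum
sufficient statistic, and conditionally on the group sums the configuration
is uniform over the compatible sign placements (within-group
exchangeability).  Exact i.i.d. sampling therefore proceeds in two stages:

1. draw a group-sum vector from its exact pushforward distribution
   (enumerated once, cost ``prod_l (N_l + 1)``),
2. choose uniformly at random which ``(N_l + s_l)/2`` members of group
   ``l`` vote +1.

This permits exact sampling for populations in the thousands when the
number of groups is small, which the asymptotic validation tests require.
A single-site heat-bath Gibbs chain is provided as an *approximate*
fallback for models whose sufficient-statistic space exceeds the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import (
    DEFAULT_STATE_CAP,
    BlockSpinModel,
    BlockSpinError,
    StateSpaceCapError,
    _sum_support,
)

__all__ = [
    "SumDistribution",
    "SampleMatrix",
    "group_sum_distribution",
    "draw_sample",
    "gibbs_draw_sample",
]


@dataclass(frozen=True)
class SumDistribution:
    """Exact law of the group-sum vector ``(s_1, .., s_M)``.

    ``support`` has shape ``(K, M)`` with ``K = prod_l (N_l + 1)``;
    ``log_weights`` are the aligned normalised log-probabilities.
    """

    support: np.ndarray
    log_weights: np.ndarray

    @property
    def probabilities(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def moment2(self) -> np.ndarray:
        """Second-moment matrix ``E[s_l s_m]`` (used by the exact oracle)."""
        w = self.probabilities
        return np.einsum("k,kl,km->lm", w, self.support, self.support)


@dataclass(frozen=True)
class SampleMatrix:
    """``n x N`` matrix of +-1 observations with provenance metadata."""

    data: np.ndarray
    seed: int | None
    method: str
    model_digest: str
    chain_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2 or data.shape[0] < 1:
            raise BlockSpinError("sample must be a 2-d matrix with n >= 1 rows")
        if not np.all(np.abs(data) == 1):
            raise BlockSpinError("sample entries must be -1 or +1")
        object.__setattr__(self, "data", data.astype(np.int8))

    @property
    def n(self) -> int:
        return int(self.data.shape[0])

    @property
    def N(self) -> int:
        return int(self.data.shape[1])


def group_sum_distribution(
    model: BlockSpinModel, cap: int = DEFAULT_STATE_CAP
) -> SumDistribution:
    """Exact pushforward of the Gibbs measure under the group-sum statistic.

    The weight of a sum vector ``s`` is
    ``prod_l C(N_l, (N_l+s_l)/2) * exp(1/2 sum_{l,m} J_lm s_l s_m / sqrt(N_l N_m))``,
    normalised by log-sum-exp (log-space binomials via log-gamma, so there is
    no under/overflow up to the state-space cap).
    """
    budget = np.prod(model.sizes + 1.0)
    if budget > cap:
        raise StateSpaceCapError(
            f"state space {budget:.3g} exceeds cap {cap:g}; use gibbs_draw_sample"
        )
    S, logc = _sum_support(model.sizes)
    sc = S / np.sqrt(model.sizes)
    logw = logc + 0.5 * np.einsum("kl,lm,km->k", sc, model.J, sc)
    logw -= logsumexp(logw)
    return SumDistribution(support=S.astype(np.int64), log_weights=logw)


def _place_spins(
    rng: np.random.Generator,
    sums: np.ndarray,
    model: BlockSpinModel,
) -> np.ndarray:
    """Uniformly random within-group placement of the +1 votes.

    Given per-row group sums, group ``l`` receives ``k = (N_l + s_l)/2``
    votes of +1 at a uniformly random subset of its member positions
    (rank trick: the k smallest of N_l i.i.d. uniforms are the +1 slots).
    Groups are processed in label order 0..M-1; this ordering is part of
    the reproducibility contract.
    """
    n = sums.shape[0]
    X = np.empty((n, model.N), dtype=np.int8)
    for l in range(model.M):
        cols = model.structure.members(l)
        size = model.sizes[l]
        k = ((sums[:, l] + size) // 2).astype(np.int64)
        u = rng.random((n, size))
        order = np.argsort(u, axis=1)
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(size)[None, :].repeat(n, 0), axis=1)
        X[:, cols] = np.where(ranks < k[:, None], 1, -1)
    return X


def draw_sample(
    model: BlockSpinModel,
    n: int,
    seed: int,
    cap: int = DEFAULT_STATE_CAP,
) -> SampleMatrix:
    """Draw ``n`` exact i.i.d. observations from the model.

    One PCG64 stream seeded with ``seed`` is consumed in documented order:
    first the ``n`` categorical group-sum draws, then the within-group
    placements for groups 0..M-1.
    """
    if n < 1:
        raise BlockSpinError("n must be >= 1")
    dist = group_sum_distribution(model, cap=cap)
    rng = np.random.default_rng(seed)
    probs = dist.probabilities
    # guard against round-off in the categorical draw
    probs = probs / probs.sum()
    idx = rng.choice(dist.support.shape[0], size=n, p=probs)
    sums = dist.support[idx]
    X = _place_spins(rng, sums, model)
    return SampleMatrix(data=X, seed=int(seed), method="exact", model_digest=model.digest())


def gibbs_draw_sample(
    model: BlockSpinModel,
    n: int,
    seed: int,
    burn_in: int | None = None,
    thin: int | None = None,
) -> SampleMatrix:
    """Approximate sampling by single-site heat-bath Gibbs dynamics.

    ``burn_in`` and ``thin`` are counted in single-site updates and default
    to ``100*N`` and ``10*N``.  Rows are *not* independent draws from the
    Gibbs measure (the chain is only asymptotically correct); the returned
    metadata flags the method as approximate.  The exact sampler is always
    preferred when the sufficient-statistic space is within the cap.
    """
    if burn_in is None:
        burn_in = 100 * model.N
    if thin is None:
        thin = 10 * model.N
    if burn_in < 1 or thin < 1 or n < 1:
        raise BlockSpinError("n, burn_in and thin must be >= 1")

    rng = np.random.default_rng(seed)
    N, M = model.N, model.M
    labels = model.labels
    Js = model.J / np.sqrt(np.outer(model.sizes, model.sizes))  # M x M scaled coupling
    x = rng.choice(np.array([-1, 1], dtype=np.int64), size=N)
    s = np.bincount(labels, weights=x, minlength=M)

    def update(steps: int) -> None:
        nonlocal x, s
        sites = rng.integers(0, N, size=steps)
        us = rng.random(steps)
        for site, u in zip(sites, us):
            g = labels[site]
            # local field of site excluding its own spin
            b = Js[g] @ s - Js[g, g] * x[site]
            p_plus = 0.5 * (1.0 + np.tanh(b))
            new = 1 if u < p_plus else -1
            if new != x[site]:
                s[g] += new - x[site]
                x[site] = new

    update(burn_in)
    rows = np.empty((n, N), dtype=np.int8)
    rows[0] = x
    for t in range(1, n):
        update(thin)
        rows[t] = x
    return SampleMatrix(
        data=rows,
        seed=int(seed),
        method="gibbs",
        model_digest=model.digest(),
        chain_params={"burn_in": int(burn_in), "thin": int(thin)},
    )
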