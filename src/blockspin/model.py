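"""Block spin Ising model: group structure, coupling matrix, Gibbs measure.

A population of ``N`` individuals is partitioned into ``M`` latent groups.
Each observation (an election, referendum, or binary measurement) is a
configuration ``x in {-1,+1}^N`` drawn from the Gibbs measure

    P(x) = Z^{-1} exp(-H(x)),
    H(x) = -1/2 sum_{l,m} J_lm / sqrt(N_l N_m) * s_l(x) s_m(x),

where ``s_l(x)`` is the sum of the spins in group ``l`` and ``J`` is a
symmetric positive-definite ``M x M`` coupling matrix.  The double sum in
the Hamiltonian runs over all index pairs including ``i == j``, so the
group-sum factorisation above is exact (the diagonal terms contribute a
configuration-independent shift that cancels in ``P`` but is retained in
raw energies).

For ``M == 1`` the model reduces to the classical Curie-Weiss model with
inverse temperature ``beta = J[0, 0]``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "BlockSpinError",
    "CriticalRegimeError",
    "StateSpaceCapError",
    "NonIdentifiableError",
    "GroupStructure",
    "CouplingMatrix",
    "BlockSpinModel",
    "Regime",
    "build_model",
    "hamiltonian",
    "classify_regime",
    "log_probability",
]

#: default cap on the sufficient-statistic state space prod_l (N_l + 1)
DEFAULT_STATE_CAP = 5_000_000


class BlockSpinError(ValueError):
    """Base class for model specification and regime errors."""


class CriticalRegimeError(BlockSpinError):
    """The model is (numerically) critical; the requested analysis is undefined."""


class StateSpaceCapError(BlockSpinError):
    """The sufficient-statistic state space exceeds the configured cap."""


class NonIdentifiableError(BlockSpinError):
    """Two groups share identical limiting correlations; detection is impossible."""


@dataclass(frozen=True)
class GroupStructure:
    """Partition of ``N`` individuals into ``M`` groups.

    Parameters
    ----------
    sizes : ndarray of int, shape (M,)
        Group sizes ``N_1 .. N_M``; every group must have at least two
        members.
    labels : ndarray of int, shape (N,)
        Group index (0-based) of each individual.  Defaults to contiguous
        blocks: the first ``N_1`` individuals form group 0, and so on.
    """

    sizes: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=np.int64)
        if sizes.ndim != 1 or sizes.size == 0:
            raise BlockSpinError("sizes must be a nonempty 1-d sequence")
        if np.any(sizes < 2):
            raise BlockSpinError("every group needs at least two individuals")
        object.__setattr__(self, "sizes", sizes)
        if self.labels is None:
            labels = np.repeat(np.arange(sizes.size), sizes)
        else:
            labels = np.asarray(self.labels, dtype=np.int64)
            if labels.shape != (int(sizes.sum()),):
                raise BlockSpinError("labels must have length N = sum(sizes)")
            counts = np.bincount(labels, minlength=sizes.size)
            if labels.min() < 0 or labels.max() >= sizes.size or not np.array_equal(counts, sizes):
                raise BlockSpinError("labels inconsistent with sizes")
        object.__setattr__(self, "labels", labels)

    @property
    def N(self) -> int:
        return int(self.sizes.sum())

    @property
    def M(self) -> int:
        return int(self.sizes.size)

    @property
    def alphas(self) -> np.ndarray:
        """Group size fractions ``alpha_l = N_l / N``."""
        return self.sizes / self.N

    def members(self, l: int) -> np.ndarray:
        """Indices of the individuals in group ``l``."""
        return np.flatnonzero(self.labels == l)


@dataclass(frozen=True)
class CouplingMatrix:
    """Symmetric positive-definite coupling matrix ``J``.

    The input is required to be symmetric up to ``1e-12 * max|J|`` and is
    then symmetrised by averaging; positive definiteness is enforced with a
    spectral tolerance of ``1e-10 * max|eigenvalue|``.
    """

    J: np.ndarray

    def __post_init__(self) -> None:
        J = np.asarray(self.J, dtype=float)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise BlockSpinError("J must be a square matrix")
        scale = np.abs(J).max()
        if scale == 0 or np.abs(J - J.T).max() > 1e-12 * scale:
            raise BlockSpinError("J must be symmetric")
        J = 0.5 * (J + J.T)
        eigs = np.linalg.eigvalsh(J)
        if eigs.min() <= 1e-10 * np.abs(eigs).max():
            raise BlockSpinError(
                f"J must be positive definite (min eigenvalue {eigs.min():.3e})"
            )
        object.__setattr__(self, "J", J)

    @property
    def M(self) -> int:
        return int(self.J.shape[0])


@dataclass(frozen=True)
class Regime:
    """Spectral classification of ``I - J``.

    ``tag`` is ``"high"`` (all eigenvalues of ``I - J`` positive: weakly
    coupled, disordered), ``"low"`` (some eigenvalue negative: strongly
    coupled, ordered phases exist) or ``"critical"`` (an eigenvalue
    vanishes within tolerance; excluded from all detection theory).
    """

    tag: str
    eigenvalues: np.ndarray


@dataclass(frozen=True)
class BlockSpinModel:
    """A group structure together with a coupling matrix."""

    structure: GroupStructure
    coupling: CouplingMatrix

    def __post_init__(self) -> None:
        if self.structure.M != self.coupling.M:
            raise BlockSpinError("structure and coupling dimensions differ")

    # -- convenience proxies -------------------------------------------------
    @property
    def N(self) -> int:
        return self.structure.N

    @property
    def M(self) -> int:
        return self.structure.M

    @property
    def sizes(self) -> np.ndarray:
        return self.structure.sizes

    @property
    def labels(self) -> np.ndarray:
        return self.structure.labels

    @property
    def alphas(self) -> np.ndarray:
        return self.structure.alphas

    @property
    def J(self) -> np.ndarray:
        return self.coupling.J

    def regime(self, tol: float | None = None) -> Regime:
        return classify_regime(self.J, tol=tol)

    def hamiltonian(self, config: np.ndarray) -> float:
        return hamiltonian(self, config)

    def log_probability(self, config: np.ndarray, cap: int = DEFAULT_STATE_CAP) -> float:
        return log_probability(self, config, cap=cap)

    def sample(self, n: int, seed: int, cap: int = DEFAULT_STATE_CAP):
        """Draw ``n`` exact i.i.d. observations; see :func:`blockspin.sampler.draw_sample`."""
        from .sampler import draw_sample

        return draw_sample(self, n, seed, cap=cap)

    def digest(self) -> str:
        """Short content hash used for sample provenance."""
        h = hashlib.sha256()
        h.update(self.sizes.tobytes())
        h.update(self.labels.tobytes())
        h.update(np.ascontiguousarray(self.J).tobytes())
        return h.hexdigest()[:12]


def build_model(
    sizes, J, labels=None
) -> BlockSpinModel:
    """Validate and assemble a block spin Ising model.

    Parameters
    ----------
    sizes : sequence of int
        Group sizes, each at least 2.
    J : array-like, shape (M, M)
        Symmetric positive-definite coupling matrix.
    labels : sequence of int, optional
        0-based group index per individual; defaults to contiguous blocks.
    """
    structure = GroupStructure(np.asarray(sizes), None if labels is None else np.asarray(labels))
    coupling = CouplingMatrix(np.asarray(J, dtype=float))
    return BlockSpinModel(structure, coupling)


def _check_config(model: BlockSpinModel, config) -> np.ndarray:
    x = np.asarray(config)
    if x.shape != (model.N,):
        raise BlockSpinError(f"configuration must have length N={model.N}")
    if not np.all(np.abs(x) == 1):
        raise BlockSpinError("configuration entries must be -1 or +1")
    return x.astype(np.int64)


def group_sums(model: BlockSpinModel, config) -> np.ndarray:
    """Sufficient statistic: per-group spin sums ``s_l = sum_{i in group l} x_i``."""
    x = _check_config(model, config)
    return np.bincount(model.labels, weights=x, minlength=model.M)


def hamiltonian(model: BlockSpinModel, config) -> float:
    """Energy of a configuration (dimensionless), diagonal terms included."""
    s = group_sums(model, config)
    sc = s / np.sqrt(model.sizes)
    return float(-0.5 * sc @ model.J @ sc)


def classify_regime(J, tol: float | None = None) -> Regime:
    """Classify ``I - J`` as high / critical / low temperature.

    ``tol`` defaults to ``1e-10`` times the spectral scale of the problem
    (the largest absolute eigenvalue of ``J`` and ``I - J``), so couplings
    within 1e-10 of the critical surface are reported as critical.
    """
    J = CouplingMatrix(np.asarray(J, dtype=float)).J
    eigs = np.sort(np.linalg.eigvalsh(np.eye(J.shape[0]) - J))
    if tol is None:
        scale = max(np.abs(eigs).max(), float(np.abs(np.linalg.eigvalsh(J)).max()))
        tol = max(1e-10 * scale, 1e-300)
    if eigs[0] > tol:
        tag = "high"
    elif eigs[0] < -tol:
        tag = "low"
    else:
        tag = "critical"
    return Regime(tag=tag, eigenvalues=eigs)


def log_partition(model: BlockSpinModel, cap: int = DEFAULT_STATE_CAP) -> float:
    """``ln Z`` by exact summation over the group-sum sufficient statistic.

    The Gibbs weight depends on a configuration only through the vector of
    group sums ``s``; a value ``s`` is attained by ``prod_l C(N_l, k_l)``
    configurations with ``k_l = (N_l + s_l)/2``, so

        Z = sum_s prod_l C(N_l, k_l) * exp(1/2 sum_{l,m} J_lm s_l s_m / sqrt(N_l N_m)).

    Cost is ``prod_l (N_l + 1)`` instead of ``2^N``.
    """
    sizes = model.sizes
    budget = np.prod(sizes + 1.0)
    if budget > cap:
        raise StateSpaceCapError(
            f"state space {budget:.3g} exceeds cap {cap:g}; use the Gibbs sampler"
        )
    S, logc = _sum_support(sizes)
    sc = S / np.sqrt(sizes)
    quad = 0.5 * np.einsum("kl,lm,km->k", sc, model.J, sc)
    return float(logsumexp(logc + quad))


def _sum_support(sizes: np.ndarray):
    """All group-sum vectors with their log multiplicities.

    Returns ``(S, logc)`` where ``S`` is ``(K, M)`` with ``K = prod(N_l+1)``
    and ``logc[k] = sum_l ln C(N_l, (N_l + S[k,l])/2)``.
    """
    grids = np.meshgrid(*[np.arange(-n, n + 1, 2) for n in sizes], indexing="ij")
    S = np.stack([g.ravel() for g in grids], axis=1).astype(np.float64)
    k = (S + sizes) / 2.0
    logc = np.zeros(S.shape[0])
    for l, n in enumerate(sizes):
        logc += gammaln(n + 1) - gammaln(k[:, l] + 1) - gammaln(n - k[:, l] + 1)
    return S, logc


def log_probability(model: BlockSpinModel, config, cap: int = DEFAULT_STATE_CAP) -> float:
    """Exact ``ln P(x)`` under the Gibbs measure."""
    return -hamiltonian(model, config) - log_partition(model, cap=cap)
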