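"""Community detection from empirical pair correlations.

The only statistic the algorithm consumes is the matrix of empirical pair
correlations ``ybar[i, j] = (1/n) sum_t x_i(t) x_j(t)``.  Theory predicts
that for a typical sample every ``ybar[i, j]`` lies within a half-width
``w`` of the limiting correlation level of the group pair ``(iota(i),
iota(j))``, and that same-group levels are separated from every other
level by more than ``2w``.  Groups are then recovered by an iterative
window recursion over the sorted distinct same-group levels
``h_(1) > ... > h_(q)``:

    G_1   = pairs whose correlation lies in the window around h_(1)
    A_1   = pairs sharing an index with a pair of G_1
    G_u+1 = pairs outside A_u whose correlation lies in the window
            around h_(u+1), and so on.

The connected components of the union of the ``G_u`` are the recovered
classes.  The recursion is implemented literally on pairs (rather than
clustering individuals directly) so the correctness argument carries over;
windows are closed intervals.  High and low temperature differ only in the
levels (``level_matrix[l, l]/N`` vs ``||Z_l||^2``) and half-width
(``delta_L/(4N)`` vs ``gamma/4``) and share one code path.

Atypical samples (the large-deviation event) are reported through
``status='inconsistent_sample'`` with diagnostics instead of raising, so
batch experiments can count failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .model import BlockSpinModel, BlockSpinError, CriticalRegimeError
from .sampler import SampleMatrix
from .landscape import (
    HighTempTheory,
    Landscape,
    find_minima,
    pair_limit_high,
    separation_constants,
)

__all__ = [
    "CorrelationMatrix",
    "LevelSpec",
    "GroupingResult",
    "empirical_correlations",
    "identify_groups",
    "label_classes",
    "identify_groups_agnostic",
    "CommunityDetector",
    "AgnosticCommunityDetector",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric ``N x N`` matrix of empirical pair correlations (diagonal unused)."""

    ybar: np.ndarray
    n: int

    def __post_init__(self) -> None:
        y = np.asarray(self.ybar, dtype=float)
        if y.ndim != 2 or y.shape[0] != y.shape[1]:
            raise BlockSpinError("ybar must be square")
        if not np.allclose(y, y.T, atol=1e-12):
            raise BlockSpinError("ybar must be symmetric")
        off = y[~np.eye(y.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise BlockSpinError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "ybar", y)

    @property
    def N(self) -> int:
        return int(self.ybar.shape[0])


def empirical_correlations(sample: SampleMatrix | np.ndarray) -> CorrelationMatrix:
    """``ybar = X^T X / n`` for an ``n x N`` matrix of +-1 observations."""
    X = sample.data if isinstance(sample, SampleMatrix) else np.asarray(sample)
    if X.ndim != 2 or X.shape[0] < 1:
        raise BlockSpinError("sample must be a 2-d matrix with n >= 1 rows")
    if not np.all(np.abs(X) == 1):
        raise BlockSpinError("sample entries must be -1 or +1")
    n = X.shape[0]
    Xf = X.astype(np.float64)
    ybar = (Xf.T @ Xf) / n
    return CorrelationMatrix(ybar=ybar, n=n)


@dataclass(frozen=True)
class LevelSpec:
    """Correlation levels and window half-widths for the recursion.

    ``levels`` must be strictly decreasing; ``halfwidths`` is either a
    scalar broadcast to all levels or one half-width per level.  Windows
    around consecutive levels must not overlap.
    """

    levels: np.ndarray
    halfwidths: np.ndarray
    regime: str = "high"

    def __post_init__(self) -> None:
        levels = np.atleast_1d(np.asarray(self.levels, dtype=float))
        hw = np.broadcast_to(np.asarray(self.halfwidths, dtype=float), levels.shape).copy()
        if np.any(np.diff(levels) >= 0):
            raise BlockSpinError("levels must be strictly decreasing")
        if np.any(hw < 0):
            raise BlockSpinError("halfwidths must be nonnegative")
        gaps = -np.diff(levels)
        if np.any(gaps <= hw[:-1] + hw[1:]):
            raise BlockSpinError("windows around consecutive levels overlap")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "halfwidths", hw)

    @property
    def q(self) -> int:
        return int(self.levels.size)

    @classmethod
    def from_high_theory(cls, theory: HighTempTheory, N: int, delta: float | None = None) -> "LevelSpec":
        """Levels = distinct diagonals of the level matrix / N; half-width delta/(4N).

        ``delta`` defaults to the separation constant of the level matrix,
        so the half-width is ``delta_L / (4N)`` on the same (alpha-scaled)
        scale as the levels.
        """
        if delta is None:
            delta = separation_constants(theory).value
        diag = np.diag(theory.level_matrix)
        levels = np.unique(np.round(diag, 12))[::-1] / N
        hw = 0.0 if delta == np.inf else delta / (4.0 * N)
        return cls(levels=levels, halfwidths=hw if delta != np.inf else np.abs(levels).max() + 1.0, regime="high")

    @classmethod
    def from_landscape(cls, landscape: Landscape, gamma: float | None = None) -> "LevelSpec":
        """Levels = distinct ``||Z_l||^2``; half-width gamma/4."""
        if gamma is None:
            gamma = separation_constants(landscape).value
        diag = np.diag(landscape.gram)
        levels = np.unique(np.round(diag, 12))[::-1]
        hw = np.abs(levels).max() + 1.0 if gamma == np.inf else gamma / 4.0
        return cls(levels=levels, halfwidths=hw, regime="low")


@dataclass(frozen=True)
class GroupingResult:
    """Recovered partition of the individuals.

    ``classes`` is a tuple of sorted index arrays; ``class_level[c]`` is
    the (0-based) level index of class ``c``; ``labels`` maps every
    individual to its class id (-1 when unassigned).  ``labels_hat`` maps
    class id -> model group index once :func:`label_classes` has run.
    """

    classes: tuple
    class_level: tuple
    labels: np.ndarray
    status: str
    diagnostics: dict
    labels_hat: tuple | None = None
    ambiguous: bool = False

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def as_partition(self) -> frozenset:
        """Label-invariant canonical form (for comparing to a planted partition)."""
        return frozenset(frozenset(int(i) for i in cls) for cls in self.classes)


def identify_groups(corr: CorrelationMatrix, spec: LevelSpec) -> GroupingResult:
    """Run the iterative window recursion and extract equivalence classes.

    For each level ``u`` (in decreasing order) the pairs whose correlation
    lies in the closed window around ``levels[u]`` *and* whose endpoints are
    untouched by earlier levels form the edge set ``G_u``; classes are the
    connected components of the union of the ``G_u``.  The sample is flagged
    inconsistent when an individual remains unassigned after the last level
    or a within-class pair falls outside its class window.
    """
    y = corr.ybar
    N = corr.N
    iu, ju = np.triu_indices(N, k=1)
    vals = y[iu, ju]

    used = np.zeros(N, dtype=bool)
    edge_level = {}
    edges_i, edges_j, edges_u = [], [], []
    per_level_counts = []
    for u in range(spec.q):
        in_window = np.abs(vals - spec.levels[u]) <= spec.halfwidths[u]
        eligible = in_window & ~used[iu] & ~used[ju]
        ei, ej = iu[eligible], ju[eligible]
        per_level_counts.append(int(ei.size))
        edges_i.append(ei)
        edges_j.append(ej)
        edges_u.append(np.full(ei.size, u))
        used[ei] = True
        used[ej] = True

    ei = np.concatenate(edges_i) if edges_i else np.empty(0, dtype=int)
    ej = np.concatenate(edges_j) if edges_j else np.empty(0, dtype=int)
    eu = np.concatenate(edges_u) if edges_u else np.empty(0, dtype=int)

    adj = coo_matrix((np.ones(ei.size), (ei, ej)), shape=(N, N))
    n_comp, comp = connected_components(adj, directed=False)

    # components that received at least one edge are classes; the rest are
    # unassigned individuals
    has_edge = np.zeros(N, dtype=bool)
    has_edge[ei] = True
    has_edge[ej] = True
    class_ids = np.unique(comp[has_edge])
    remap = {int(c): k for k, c in enumerate(class_ids)}
    labels = np.full(N, -1, dtype=int)
    for i in range(N):
        if has_edge[i]:
            labels[i] = remap[comp[i]]

    classes = tuple(np.flatnonzero(labels == k) for k in range(len(class_ids)))

    # each class inherits the level of its edges; by construction edges of
    # one component share a single level (later windows exclude any vertex
    # already touched), but verify and flag if violated
    class_level = []
    mixed_levels = 0
    for k, cls in enumerate(classes):
        mask = (labels[ei] == k)
        lv = np.unique(eu[mask])
        if lv.size != 1:
            mixed_levels += 1
        class_level.append(int(lv[0]))

    # within-class window consistency: every pair inside a class must lie in
    # the window of that class's level
    out_of_window = 0
    for k, cls in enumerate(classes):
        if cls.size < 2:
            continue
        ci, cj = np.triu_indices(cls.size, k=1)
        v = y[cls[ci], cls[cj]]
        out_of_window += int(
            np.sum(np.abs(v - spec.levels[class_level[k]]) > spec.halfwidths[class_level[k]])
        )

    unassigned = np.flatnonzero(labels < 0)
    status = "success"
    if unassigned.size or mixed_levels or out_of_window:
        status = "inconsistent_sample"

    diagnostics = {
        "per_level_edge_counts": per_level_counts,
        "unassigned": unassigned.tolist(),
        "mixed_level_classes": mixed_levels,
        "out_of_window_pairs": out_of_window,
        "levels": spec.levels.tolist(),
        "halfwidths": spec.halfwidths.tolist(),
        "regime": spec.regime,
    }
    return GroupingResult(
        classes=classes,
        class_level=tuple(class_level),
        labels=labels,
        status=status,
        diagnostics=diagnostics,
    )


def label_classes(
    result: GroupingResult,
    theory: HighTempTheory | Landscape,
    sizes=None,
) -> GroupingResult:
    """Match recovered classes to model group indices.

    A class at level ``u`` can be labelled uniquely when a single group sits
    at that level; otherwise group sizes (when supplied and distinct within
    the level) break the tie; otherwise a valid labelling is returned with
    ``ambiguous=True``.
    """
    if result.status != "success":
        raise BlockSpinError("cannot label classes of an inconsistent sample")
    if isinstance(theory, HighTempTheory):
        diag = np.diag(theory.level_matrix)
    else:
        diag = np.diag(theory.gram)
    M = diag.size
    if result.n_classes != M:
        raise BlockSpinError(
            f"detected {result.n_classes} classes but the model has {M} groups"
        )
    levels = np.unique(np.round(diag, 12))[::-1]
    group_level = np.array([int(np.argmin(np.abs(levels - d))) for d in diag])

    labels_hat = [None] * result.n_classes
    ambiguous = False
    for u in range(levels.size):
        cls_at_u = [k for k in range(result.n_classes) if result.class_level[k] == u]
        groups_at_u = list(np.flatnonzero(group_level == u))
        if len(cls_at_u) != len(groups_at_u):
            raise BlockSpinError("class/group count mismatch within a level")
        if len(groups_at_u) == 1:
            labels_hat[cls_at_u[0]] = groups_at_u[0]
            continue
        if sizes is not None:
            sizes_arr = np.asarray(sizes)
            remaining = list(groups_at_u)
            matched = {}
            for k in sorted(cls_at_u, key=lambda k: -result.classes[k].size):
                fits = [g for g in remaining if sizes_arr[g] == result.classes[k].size]
                if len(fits) == 1:
                    matched[k] = fits[0]
                    remaining.remove(fits[0])
            if len(matched) == len(cls_at_u):
                for k, g in matched.items():
                    labels_hat[k] = g
                continue
        # unresolvable within this level: assign in order, flag ambiguity
        ambiguous = True
        for k, g in zip(cls_at_u, groups_at_u):
            labels_hat[k] = g

    return GroupingResult(
        classes=result.classes,
        class_level=result.class_level,
        labels=result.labels,
        status=result.status,
        diagnostics=result.diagnostics,
        labels_hat=tuple(labels_hat),
        ambiguous=ambiguous,
    )


def _gap_split_threshold(sorted_vals: np.ndarray) -> float:
    """Default band threshold: split the sorted gaps at their largest ratio jump."""
    gaps = np.diff(sorted_vals)
    gaps = gaps[gaps > 0]
    if gaps.size < 2:
        return np.inf
    g = np.sort(gaps)
    floor = max(g[-1] * 1e-12, 1e-15)
    ratios = (g[1:] + floor) / (g[:-1] + floor)
    k = int(np.argmax(ratios))
    if ratios[k] < 3.0:  # no clear scale separation: treat as one band
        return np.inf
    return float(np.sqrt((g[k] + floor) * (g[k + 1] + floor)))


def identify_groups_agnostic(
    corr: CorrelationMatrix, min_gap: float | None = None
) -> GroupingResult:
    """Model-free banding heuristic (no theoretical guarantee).

    Sorts the ``N(N-1)/2`` correlations, splits them at gaps larger than
    ``min_gap`` into bands, and runs the window recursion with band centres
    as levels and band half-ranges as half-widths.  If the resulting
    partition is inconsistent, the two bands separated by the smallest gap
    are merged and the recursion is retried, down to a single band (which
    always yields one class).  ``min_gap`` defaults to a largest-gap-ratio
    split of the sorted values.
    """
    y = corr.ybar
    N = corr.N
    iu, ju = np.triu_indices(N, k=1)
    vals = np.sort(y[iu, ju])
    if min_gap is None:
        min_gap = _gap_split_threshold(vals)

    # initial bands: maximal runs with internal gaps <= min_gap
    splits = np.flatnonzero(np.diff(vals) > min_gap)
    bounds = [0, *list(splits + 1), vals.size]
    bands = [(vals[a], vals[b - 1]) for a, b in zip(bounds[:-1], bounds[1:])]

    while True:
        levels = np.array([(lo + hi) / 2.0 for lo, hi in bands])[::-1]
        hws = np.array([(hi - lo) / 2.0 for lo, hi in bands])[::-1]
        # pad half-widths so boundary values (ties) stay inside, then shrink
        # any overlap created by padding
        pad = max(1e-12, 1e-9 * (np.abs(vals).max() + 1))
        hws = hws + pad
        if levels.size > 1:
            gaps = -np.diff(levels)
            scale = np.minimum(1.0, gaps / (hws[:-1] + hws[1:] + pad))
            hws[:-1] *= np.minimum(1.0, np.append(scale, 1.0)[: hws.size - 1])
            hws[1:] *= scale
        try:
            spec = LevelSpec(levels=levels, halfwidths=hws, regime="agnostic")
            result = identify_groups(corr, spec)
        except BlockSpinError:
            result = None
        if result is not None and result.status == "success":
            # §-style sanity: a top band must consist of k(k-1)/2 pairs of k members
            sizes_ok = all(
                cls.size * (cls.size - 1) // 2 >= 1 for cls in result.classes
            )
            if sizes_ok:
                return result
        if len(bands) == 1:
            raise BlockSpinError("no admissible banding found")
        # merge the two bands separated by the smallest gap and retry
        gaps = [bands[k + 1][0] - bands[k][1] for k in range(len(bands) - 1)]
        k = int(np.argmin(gaps))
        bands[k : k + 2] = [(bands[k][0], bands[k + 1][1])]


# --------------------------------------------------------------------------
# sklearn-style estimators (cluster the columns of an n x N sample matrix)
# --------------------------------------------------------------------------


class CommunityDetector(BaseEstimator):
    """Recover the latent group partition from a sample of +-1 observations.

    The estimator clusters the *columns* (individuals) of an ``n x N``
    sample matrix, in the spirit of feature agglomeration.  The correlation
    levels and window half-widths are derived from the supplied generative
    model: high temperature uses the inverse-coupling theory, low
    temperature the free-energy landscape.

    Parameters
    ----------
    model : BlockSpinModel
        The assumed generative model (only its coupling matrix and group
        size fractions are used, never the planted labels).
    regime : {"auto", "high", "low"}
        Force a regime or infer it from the spectrum of ``I - J``.

    Attributes
    ----------
    labels_ : ndarray of shape (N,)
        Class index per individual (-1 if unassigned).
    result_ : GroupingResult
        Full partition with diagnostics and group labels.
    level_spec_ : LevelSpec
        The windows used.
    theory_ : HighTempTheory or Landscape
        The asymptotic theory object.
    """

    def __init__(self, model: BlockSpinModel = None, regime: str = "auto"):
        self.model = model
        self.regime = regime

    def fit(self, X, y=None):
        if self.model is None:
            raise BlockSpinError("CommunityDetector requires a model")
        corr = empirical_correlations(np.asarray(X))
        tag = self.regime
        if tag == "auto":
            tag = self.model.regime().tag
        if tag == "critical":
            raise CriticalRegimeError("detection is undefined in the critical regime")
        if tag == "high":
            self.theory_ = pair_limit_high(self.model)
            self.level_spec_ = LevelSpec.from_high_theory(self.theory_, N=corr.N)
        else:
            self.theory_ = find_minima(self.model)
            self.level_spec_ = LevelSpec.from_landscape(self.theory_)
        result = identify_groups(corr, self.level_spec_)
        if result.status == "success":
            result = label_classes(result, self.theory_, sizes=self.model.sizes)
        self.result_ = result
        self.labels_ = result.labels
        self.correlations_ = corr
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class AgnosticCommunityDetector(BaseEstimator):
    """Model-free column clustering by correlation banding (heuristic).

    Parameters
    ----------
    min_gap : float or None
        Minimum gap between correlation bands; ``None`` selects it by the
        largest-gap-ratio rule.
    """

    def __init__(self, min_gap: float | None = None):
        self.min_gap = min_gap

    def fit(self, X, y=None):
        corr = empirical_correlations(np.asarray(X))
        self.result_ = identify_groups_agnostic(corr, min_gap=self.min_gap)
        self.labels_ = self.result_.labels
        self.correlations_ = corr
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
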