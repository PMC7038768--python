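"""Fuzzy c-means (FCM) machinery for range-scan clustering.

A downward-pointing ultrasonic sensor scanning over crop plants returns a
stream of distances that cluster into layers: canopy, lower leaves, ground.
This module holds the FCM containers and the alternating minimization of the
weighted within-cluster squared-distance objective

    J(U, V) = sum_i sum_j u_ij**q * ||X_j - V_i||**2

with membership and center updates derived from the stationarity conditions
of the constrained problem (columns of U summing to one).  All equations are
stated for general feature dimension ``d``; range scans use ``d = 1`` (cm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "SampleSet",
    "CenterSet",
    "FuzzyPartition",
    "FcmState",
    "DegenerateClusterError",
    "update_centers",
    "update_memberships",
    "membership_matrix",
    "objective",
    "fcm_converge",
    "quantile_centers",
    "random_centers",
    "crisp_partition_from_centers",
    "nearest_center_labels",
]

#: column sums of a fuzzy partition must match 1 to this tolerance
_COLSUM_TOL = 1e-9


class DegenerateClusterError(RuntimeError):
    """A cluster has zero total membership, so its center is undefined."""


@dataclass(frozen=True)
class SampleSet:
    """n samples x d characteristic indicators (range scans: d = 1, cm)."""

    values: NDArray[np.float64]
    max_range: float | None = None

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.values, dtype=float))
        if arr.ndim != 2:
            raise ValueError("sample values must form an n x d matrix")
        object.__setattr__(self, "values", arr)
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if arr.shape[1] < 1:
            raise ValueError("need at least 1 characteristic indicator")
        if not np.all(np.isfinite(arr)):
            raise ValueError("sample values must be finite")
        if self.max_range is not None:
            if np.any(arr <= 0) or np.any(arr > self.max_range):
                raise ValueError(
                    f"range samples must lie in (0, {self.max_range}] cm"
                )

    @classmethod
    def from_distances(
        cls, distances: ArrayLike, max_range: float | None = None
    ) -> "SampleSet":
        """Build a 1-D sample set from a sequence of range readings (cm)."""
        arr = np.asarray(distances, dtype=float).reshape(-1, 1)
        return cls(arr, max_range=max_range)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CenterSet:
    """c cluster center vectors, one row per cluster."""

    centers: NDArray[np.float64]

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "centers", arr)
        if not np.all(np.isfinite(arr)):
            raise ValueError("cluster centers must be finite")
        if arr.shape[0] < 1:
            raise ValueError("need at least one cluster center")

    @property
    def c(self) -> int:
        return self.centers.shape[0]

    @property
    def d(self) -> int:
        return self.centers.shape[1]

    def sort_order(self) -> NDArray[np.intp]:
        """Ascending order by coordinates (lexicographic for d > 1)."""
        return np.lexsort(self.centers.T[::-1])

    def sorted(self) -> "CenterSet":
        return CenterSet(self.centers[self.sort_order()])


@dataclass(frozen=True)
class FuzzyPartition:
    """c x n matrix of membership degrees u_ij in [0, 1].

    Each column sums to one (every sample's memberships form a discrete
    distribution over clusters) and each row sum lies strictly in (0, n)
    (no cluster is empty, none absorbs everything).
    """

    memberships: NDArray[np.float64]

    def __post_init__(self) -> None:
        u = np.atleast_2d(np.asarray(self.memberships, dtype=float))
        object.__setattr__(self, "memberships", u)
        if np.any(u < 0.0) or np.any(u > 1.0):
            raise ValueError("membership degrees must lie in [0, 1]")
        colsums = u.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > _COLSUM_TOL):
            raise ValueError("each partition column must sum to 1")
        rowsums = u.sum(axis=1)
        n = u.shape[1]
        if np.any(rowsums <= 0.0) or np.any(rowsums >= n):
            raise ValueError("each row sum must lie strictly in (0, n)")

    @property
    def c(self) -> int:
        return self.memberships.shape[0]

    @property
    def n(self) -> int:
        return self.memberships.shape[1]


@dataclass(frozen=True)
class FcmState:
    """Result of an FCM convergence run.

    ``objective_trace`` records J(U, V) after every completed iteration
    (centers updated from the previous partition, then memberships refreshed);
    the alternating updates make it non-increasing.
    """

    partition: FuzzyPartition
    centers: CenterSet
    objective: float
    iteration: int
    converged: bool
    objective_trace: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.objective < 0.0:
            raise ValueError("objective must be non-negative")
        if self.iteration < 0:
            raise ValueError("iteration counter must be >= 0")


def _sq_distances(samples: SampleSet, centers: CenterSet) -> NDArray[np.float64]:
    """Squared Euclidean distances, shape (c, n)."""
    return cdist(centers.centers, samples.values, metric="sqeuclidean")


def update_centers(
    samples: SampleSet, partition: FuzzyPartition, q: float = 2.0
) -> CenterSet:
    """Center update: V_i = sum_j u_ij**q X_j / sum_j u_ij**q.

    Raises :class:`DegenerateClusterError` if some cluster has zero total
    membership weight (its center would be 0/0).
    """
    if q <= 1.0:
        raise ValueError("weight exponent q must exceed 1")
    if partition.n != samples.n:
        raise ValueError("partition width must match the sample count")
    w = partition.memberships**q
    denom = w.sum(axis=1)
    dead = np.flatnonzero(denom == 0.0)
    if dead.size:
        raise DegenerateClusterError(
            f"cluster {dead[0]} has zero total membership weight"
        )
    centers = (w @ samples.values) / denom[:, None]
    return CenterSet(centers)


def membership_matrix(
    samples: SampleSet, centers: CenterSet, q: float = 2.0
) -> NDArray[np.float64]:
    """Raw membership matrix (c, n) without partition validation.

    Used by the ISODATA driver to detect centers that would receive zero
    total membership (possible when quantile initialization duplicates a
    center on noiseless data) before constructing a validated partition.
    """
    if q <= 1.0:
        raise ValueError("weight exponent q must exceed 1")
    if centers.c < 2:
        raise ValueError("membership update needs at least 2 centers")
    if centers.d != samples.d:
        raise ValueError("center and sample dimensions differ")
    d2 = _sq_distances(samples, centers)
    expo = 1.0 / (q - 1.0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = d2 ** (-expo)
        u = inv / inv.sum(axis=0)
    # Columns where a distance vanished (or underflowed past float range):
    # put all mass uniformly on the minimal-distance centers.
    bad = ~np.all(np.isfinite(u), axis=0)
    if np.any(bad):
        sub = d2[:, bad]
        tie = sub == sub.min(axis=0)
        u[:, bad] = tie / tie.sum(axis=0)
    return u


def update_memberships(
    samples: SampleSet, centers: CenterSet, q: float = 2.0
) -> FuzzyPartition:
    """Membership update u_ij = 1 / sum_p (||X_j-V_i||^2 / ||X_j-V_p||^2)^(1/(q-1)).

    Singularity convention: a sample coinciding with exactly one center gets
    membership 1 there; coinciding with m centers, membership 1/m on each.
    """
    return FuzzyPartition(membership_matrix(samples, centers, q))


def objective(
    samples: SampleSet,
    centers: CenterSet,
    partition: FuzzyPartition,
    q: float = 2.0,
) -> float:
    """J(U, V) = sum_i sum_j u_ij**q ||X_j - V_i||**2 (cm^2, summed)."""
    d2 = _sq_distances(samples, centers)
    return float(np.sum(partition.memberships**q * d2))


def fcm_converge(
    samples: SampleSet,
    initial_partition: FuzzyPartition,
    q: float = 2.0,
    epsilon: float = 1e-4,
    max_iter: int = 300,
) -> FcmState:
    """Alternate center and membership updates until the partition settles.

    One iteration recomputes centers from the current partition and then the
    partition from those centers; iteration stops when
    ``max_ij |u_ij(k+1) - u_ij(k)| <= epsilon`` or after ``max_iter``
    iterations (then ``converged`` is False and a warning is logged).
    """
    if epsilon <= 0.0:
        raise ValueError("epsilon must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    u_prev = initial_partition
    centers = update_centers(samples, u_prev, q)
    trace: list[float] = []
    converged = False
    iteration = 0
    u = u_prev
    for k in range(max_iter):
        if k > 0:
            centers = update_centers(samples, u_prev, q)
        u = update_memberships(samples, centers, q)
        trace.append(objective(samples, centers, u, q))
        iteration = k + 1
        delta = float(np.max(np.abs(u.memberships - u_prev.memberships)))
        u_prev = u
        if delta <= epsilon:
            converged = True
            break
    if not converged:
        logger.warning(
            "FCM hit the iteration cap (%d) without converging", max_iter
        )
    return FcmState(
        partition=u,
        centers=centers,
        objective=trace[-1],
        iteration=iteration,
        converged=converged,
        objective_trace=tuple(trace),
    )


def quantile_centers(samples: SampleSet, c: int) -> CenterSet:
    """Deterministic init: centers at evenly spaced quantiles of the data.

    Quantile levels (2i+1)/(2c), i = 0..c-1, applied per dimension.  On the
    layered 1-D range data this lands one seed center per dominant layer.

    Coincident centers are a frozen symmetry of the fuzzy updates (identical
    rows stay identical forever), so if the quantiles collide — short scans
    with heavily repeated values — 1-D initialization falls back to
    quantiles of the *unique* sample values, which are strictly increasing
    and hence always distinct.
    """
    if not 2 <= c <= samples.n:
        raise ValueError("need 2 <= c <= n")
    levels = (2 * np.arange(c) + 1) / (2 * c)
    centers = np.quantile(samples.values, levels, axis=0)
    if samples.d == 1 and np.unique(centers[:, 0]).size < c:
        uniq = np.unique(samples.values[:, 0])
        if uniq.size >= 2:
            centers = np.quantile(uniq, levels).reshape(-1, 1)
    return CenterSet(centers)


def random_centers(
    samples: SampleSet, c: int, rng: np.random.Generator
) -> CenterSet:
    """Seeded init: c distinct samples drawn without replacement."""
    if not 2 <= c <= samples.n:
        raise ValueError("need 2 <= c <= n")
    idx = rng.choice(samples.n, size=c, replace=False)
    return CenterSet(samples.values[idx])


def nearest_center_labels(
    samples: SampleSet, centers: CenterSet
) -> NDArray[np.intp]:
    """Index of the nearest center per sample; ties go to the lowest index."""
    d2 = _sq_distances(samples, centers)
    return np.argmin(d2, axis=0)


def crisp_partition_from_centers(
    samples: SampleSet, centers: CenterSet
) -> FuzzyPartition:
    """Crisp (0/1) partition assigning every sample to its nearest center.

    Falls back to fuzzy memberships when some center captures no sample
    (possible on noiseless data with duplicated quantile centers), so that
    the returned partition never carries an all-zero row unless the center
    is coincident-and-shadowed, which callers must handle.
    """
    labels = nearest_center_labels(samples, centers)
    u = np.zeros((centers.c, samples.n))
    u[labels, np.arange(samples.n)] = 1.0
    if np.any(u.sum(axis=1) == 0.0):
        return update_memberships(samples, centers)
    return FuzzyPartition(u)
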