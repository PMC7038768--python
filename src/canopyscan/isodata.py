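"""Fuzzy ISODATA: split/merge adjustment around converged fuzzy c-means.

The driver alternates full FCM convergence with ISODATA-style structural
moves: a cluster whose dispersion exceeds a threshold (and whose samples are
numerous and farther from their center than average) is split into two, and
cluster pairs whose centers lie closer than a minimum separation are merged.
On layered ultrasonic range data this adapts the cluster count to however
many echo layers (canopy, lower leaves, ground) the scan actually contains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

from .fuzzy_core import (
    CenterSet,
    DegenerateClusterError,
    FcmState,
    FuzzyPartition,
    SampleSet,
    crisp_partition_from_centers,
    fcm_converge,
    membership_matrix,
    nearest_center_labels,
    quantile_centers,
    random_centers,
    update_memberships,
)
from .validity import fuzzy_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "IsodataConfig",
    "ClusterStats",
    "ClusterModel",
    "SplitEvent",
    "MergeEvent",
    "DeleteEvent",
    "cluster_stats",
    "try_split",
    "try_merge",
    "hard_assign",
    "run_fuzzy_isodata",
]


@dataclass(frozen=True)
class IsodataConfig:
    """Tuning parameters of the fuzzy ISODATA driver.

    Defaults are the settings that gave the best results on known range
    data sets: ``c_init=3`` (canopy / lower leaves / ground), convergence
    threshold ``epsilon=1e-4``, weight exponent ``q=2``, minimum cluster
    population ``theta_n=20``, split standard-deviation threshold
    ``theta_s=5`` cm and minimum center separation ``theta_c=2`` cm.
    """

    c_init: int = 3
    epsilon: float = 1e-4
    q: float = 2.0
    theta_n: int = 20
    theta_s: float = 5.0
    theta_c: float = 2.0
    max_outer: int = 10
    max_inner: int = 300
    seed: int = 0
    init: str = "quantile"  # or "random" (seeded sample of c_init points)

    def __post_init__(self) -> None:
        if self.epsilon <= 0.0:
            raise ValueError("epsilon must be positive")
        if self.q <= 1.0:
            raise ValueError("q must exceed 1")
        if self.theta_n < 1:
            raise ValueError("theta_n must be >= 1")
        if self.theta_s <= 0.0 or self.theta_c <= 0.0:
            raise ValueError("theta_s and theta_c must be positive")
        if self.c_init < 2:
            raise ValueError("c_init must be >= 2")
        if self.max_outer < 1 or self.max_inner < 1:
            raise ValueError("iteration caps must be >= 1")
        if self.init not in ("quantile", "random"):
            raise ValueError("init must be 'quantile' or 'random'")


@dataclass(frozen=True)
class ClusterStats:
    """Per-cluster dispersion summaries of a hard assignment.

    ``mean_dists[i]`` is the average distance from each member of cluster i
    to its center; ``global_mean`` averages that over all n samples;
    ``sigmas[i]`` is the population (divisor n_i) standard deviation of the
    member-to-center distances, sqrt(mean ||X - V_i||^2).
    """

    counts: NDArray[np.intp]
    mean_dists: NDArray[np.float64]
    sigmas: NDArray[np.float64]
    global_mean: float
    centers: CenterSet
    split_directions: NDArray[np.float64]  # unit vector per cluster

    @property
    def c(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class SplitEvent:
    round: int
    cluster: int
    center: tuple[float, ...]
    sigma: float
    new_centers: tuple[tuple[float, ...], tuple[float, ...]]
    applied: bool = True

    def to_dict(self) -> dict:
        return {
            "event": "split",
            "round": self.round,
            "cluster": self.cluster,
            "center": list(self.center),
            "sigma": self.sigma,
            "new_centers": [list(v) for v in self.new_centers],
            "applied": self.applied,
        }


@dataclass(frozen=True)
class MergeEvent:
    round: int
    clusters: tuple[int, int]
    centers: tuple[tuple[float, ...], tuple[float, ...]]
    counts: tuple[int, int]
    distance: float
    new_center: tuple[float, ...]
    applied: bool = True

    def to_dict(self) -> dict:
        return {
            "event": "merge",
            "round": self.round,
            "clusters": list(self.clusters),
            "centers": [list(v) for v in self.centers],
            "counts": list(self.counts),
            "distance": self.distance,
            "new_center": list(self.new_center),
            "applied": self.applied,
        }


@dataclass(frozen=True)
class DeleteEvent:
    round: int
    cluster: int
    center: tuple[float, ...]
    reason: str
    applied: bool = True

    def to_dict(self) -> dict:
        return {
            "event": "delete",
            "round": self.round,
            "cluster": self.cluster,
            "center": list(self.center),
            "reason": self.reason,
            "applied": self.applied,
        }


@dataclass(frozen=True)
class ClusterModel:
    """Final fuzzy ISODATA model: sorted centers, hard labels, diagnostics."""

    centers: CenterSet
    hard_labels: NDArray[np.intp]
    stats: ClusterStats
    partition: FuzzyPartition
    entropy: float
    events: tuple = field(default_factory=tuple)
    fcm_converged: bool = True
    outer_converged: bool = True
    rounds: int = 1
    fcm_iterations: int = 0
    config: IsodataConfig | None = None

    @property
    def c(self) -> int:
        return self.centers.c

    @property
    def center_values(self) -> NDArray[np.float64]:
        """Ascending 1-D center coordinates (d = 1 models only)."""
        if self.centers.d != 1:
            raise ValueError("center_values is defined for d = 1 models")
        return self.centers.centers[:, 0]


def cluster_stats(
    samples: SampleSet, centers: CenterSet, labels: NDArray[np.intp]
) -> ClusterStats:
    """Counts, mean member-center distances and dispersions per cluster."""
    c = centers.c
    counts = np.bincount(labels, minlength=c)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"cluster {empty[0]} is empty")
    mean_dists = np.empty(c)
    sigmas = np.empty(c)
    directions = np.zeros((c, centers.d))
    for i in range(c):
        diff = samples.values[labels == i] - centers.centers[i]
        dist = np.linalg.norm(diff, axis=1)
        mean_dists[i] = dist.mean()
        sigmas[i] = np.sqrt(np.mean(dist**2))
        if centers.d == 1:
            directions[i, 0] = 1.0
        else:
            # Split displacement axis: dominant axis of within-cluster scatter.
            scatter = diff.T @ diff
            _, vecs = np.linalg.eigh(scatter)
            directions[i] = vecs[:, -1]
    global_mean = float(np.dot(counts, mean_dists) / samples.n)
    return ClusterStats(
        counts=counts,
        mean_dists=mean_dists,
        sigmas=sigmas,
        global_mean=global_mean,
        centers=centers,
        split_directions=directions,
    )


def try_split(
    stats: ClusterStats, config: IsodataConfig, round: int = 0
) -> list[SplitEvent]:
    """Propose splits: cluster i qualifies iff (all strict)

    sigma_i > theta_s,  Dbar_i > Dbar,  n_i > 2 (theta_n + 1),

    and its two replacement centers are V_i - 0.5 sigma_i and
    V_i + 0.5 sigma_i (displaced along the dominant scatter axis for d > 1).
    """
    events = []
    for i in range(stats.c):
        if (
            stats.sigmas[i] > config.theta_s
            and stats.mean_dists[i] > stats.global_mean
            and stats.counts[i] > 2 * (config.theta_n + 1)
        ):
            v = stats.centers.centers[i]
            delta = 0.5 * stats.sigmas[i] * stats.split_directions[i]
            lo, hi = v - delta, v + delta
            events.append(
                SplitEvent(
                    round=round,
                    cluster=i,
                    center=tuple(v),
                    sigma=float(stats.sigmas[i]),
                    new_centers=(tuple(lo), tuple(hi)),
                )
            )
    return events


def try_merge(
    centers: CenterSet,
    counts: NDArray[np.intp],
    config: IsodataConfig,
    round: int = 0,
) -> list[MergeEvent]:
    """Propose merges for center pairs closer than theta_c (strict).

    Pairs are processed in ascending distance order and each cluster joins
    at most one merge per round.  The merged center is the count-weighted
    mean (n_i V_i + n_j V_j) / (n_i + n_j).
    """
    c = centers.c
    if c < 2:
        return []
    pairs = []
    for i in range(c):
        for j in range(i + 1, c):
            d = float(np.linalg.norm(centers.centers[i] - centers.centers[j]))
            if d < config.theta_c:
                pairs.append((d, i, j))
    pairs.sort()
    used: set[int] = set()
    events = []
    for d, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        ni, nj = int(counts[i]), int(counts[j])
        vi, vj = centers.centers[i], centers.centers[j]
        if ni + nj == 0:
            vk = 0.5 * (vi + vj)
        else:
            vk = (ni * vi + nj * vj) / (ni + nj)
        events.append(
            MergeEvent(
                round=round,
                clusters=(i, j),
                centers=(tuple(vi), tuple(vj)),
                counts=(ni, nj),
                distance=d,
                new_center=tuple(vk),
            )
        )
    return events


def hard_assign(
    samples: SampleSet, centers: CenterSet
) -> NDArray[np.intp]:
    """Nearest-center labels; ties break to the lowest index after
    ascending-center sort.  Labels refer to the input center order."""
    if centers.c < 1:
        raise ValueError("need at least one center")
    order = centers.sort_order()
    sorted_centers = CenterSet(centers.centers[order])
    labels_sorted = nearest_center_labels(samples, sorted_centers)
    return order[labels_sorted]


def _apply_splits(
    centers: CenterSet, splits: list[SplitEvent]
) -> CenterSet:
    rows = []
    split_idx = {e.cluster: e for e in splits}
    for i in range(centers.c):
        if i in split_idx:
            lo, hi = split_idx[i].new_centers
            rows.append(np.asarray(lo))
            rows.append(np.asarray(hi))
        else:
            rows.append(centers.centers[i])
    return CenterSet(np.vstack(rows))


def _apply_merges(
    centers: CenterSet, merges: list[MergeEvent]
) -> CenterSet:
    drop = set()
    rows = [centers.centers[i].copy() for i in range(centers.c)]
    for e in merges:
        i, j = e.clusters
        rows[i] = np.asarray(e.new_center)
        drop.add(j)
    kept = [r for k, r in enumerate(rows) if k not in drop]
    return CenterSet(np.vstack(kept))


def _prune_dead_centers(
    samples: SampleSet,
    centers: CenterSet,
    q: float,
    rnd: int,
    events: list,
) -> CenterSet:
    """Drop centers that would receive zero total fuzzy membership."""
    while centers.c > 2:
        u = membership_matrix(samples, centers, q)
        dead = np.flatnonzero(u.sum(axis=1) == 0.0)
        if dead.size == 0:
            return centers
        i = int(dead[0])
        events.append(
            DeleteEvent(
                round=rnd,
                cluster=i,
                center=tuple(centers.centers[i]),
                reason="zero total membership",
            )
        )
        logger.info("round %d: deleted degenerate cluster %d", rnd, i)
        keep = np.ones(centers.c, dtype=bool)
        keep[i] = False
        centers = CenterSet(centers.centers[keep])
    u = membership_matrix(samples, centers, q)
    if np.any(u.sum(axis=1) == 0.0):
        raise DegenerateClusterError(
            "cannot reduce below 2 clusters while pruning degenerate centers"
        )
    return centers


def run_fuzzy_isodata(
    samples: SampleSet, config: IsodataConfig | None = None
) -> ClusterModel:
    """Full fuzzy ISODATA driver.

    Each outer round runs FCM to convergence, hard-assigns samples to the
    sorted centers, deletes emptied clusters, then proposes splits and
    merges.  Rounds repeat until one passes with no structural change or
    ``max_outer`` is reached.  Deterministic for a fixed config seed.
    """
    if config is None:
        config = IsodataConfig()
    if samples.n <= config.c_init:
        raise ValueError(
            f"need more than c_init={config.c_init} samples, got {samples.n}"
        )
    rng = np.random.default_rng(config.seed)
    if config.init == "quantile":
        centers = quantile_centers(samples, config.c_init)
    else:
        centers = random_centers(samples, config.c_init, rng)
    centers = centers.sorted()

    events: list = []
    total_fcm_iterations = 0
    outer_converged = False
    state: FcmState | None = None
    final: tuple | None = None
    rnd = 0
    for rnd in range(1, config.max_outer + 1):
        round_changed = False
        pruned = _prune_dead_centers(samples, centers, config.q, rnd, events)
        if pruned.c != centers.c:
            round_changed = True
        centers = pruned

        u0 = crisp_partition_from_centers(samples, centers)
        state = fcm_converge(
            samples, u0, q=config.q, epsilon=config.epsilon,
            max_iter=config.max_inner,
        )
        total_fcm_iterations += state.iteration

        order = state.centers.sort_order()
        centers = CenterSet(state.centers.centers[order])
        partition = FuzzyPartition(state.partition.memberships[order])
        labels = nearest_center_labels(samples, centers)

        counts = np.bincount(labels, minlength=centers.c)
        emptied = np.flatnonzero(counts == 0)
        if emptied.size:
            for i in emptied:
                events.append(
                    DeleteEvent(
                        round=rnd,
                        cluster=int(i),
                        center=tuple(centers.centers[i]),
                        reason="emptied by hard assignment",
                    )
                )
            if centers.c - emptied.size < 2:
                raise DegenerateClusterError(
                    "hard assignment left fewer than 2 populated clusters"
                )
            keep = counts > 0
            centers = CenterSet(centers.centers[keep])
            partition = update_memberships(samples, centers, config.q)
            labels = nearest_center_labels(samples, centers)
            round_changed = True

        stats = cluster_stats(samples, centers, labels)
        splits = try_split(stats, config, round=rnd)
        centers_after = centers
        if splits:
            centers_after = _apply_splits(centers, splits)
            labels_after = nearest_center_labels(samples, centers_after)
            counts_after = np.bincount(labels_after, minlength=centers_after.c)
        else:
            counts_after = np.bincount(labels, minlength=centers.c)
        merges = try_merge(centers_after, counts_after, config, round=rnd)

        if not (round_changed or splits or merges):
            outer_converged = True
            final = (centers, partition, labels, stats, state)
            break

        if rnd == config.max_outer:
            # Out of rounds: keep the converged model from this round and
            # log any unapplied structural proposals.
            events.extend(replace(e, applied=False) for e in splits)
            events.extend(replace(e, applied=False) for e in merges)
            if splits or merges:
                logger.warning(
                    "outer round limit (%d) reached; %d split/merge "
                    "proposals left unapplied",
                    config.max_outer,
                    len(splits) + len(merges),
                )
            final = (centers, partition, labels, stats, state)
            break

        events.extend(splits)
        events.extend(merges)
        if merges:
            centers_after = _apply_merges(centers_after, merges)
        centers = centers_after.sorted()

    assert final is not None and state is not None
    centers, partition, labels, stats, state = final
    report = fuzzy_entropy(partition)
    return ClusterModel(
        centers=centers,
        hard_labels=labels,
        stats=stats,
        partition=partition,
        entropy=report.v_pe,
        events=tuple(events),
        fcm_converged=state.converged,
        outer_converged=outer_converged,
        rounds=rnd,
        fcm_iterations=total_fcm_iterations,
        config=config,
    )
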