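"""Comparison estimators for the sensor-to-canopy distance.

Naive summaries of a range scan (mean, median) cannot exclude lower-leaf and
ground echoes and therefore overestimate the canopy distance; k-means can,
but is sensitive to its initial centers and needs the cluster count fixed in
advance.  These estimators provide that comparison on any scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.vq import kmeans2

from .fuzzy_core import SampleSet

__all__ = [
    "BaselineReport",
    "kmeans_estimate",
    "mean_estimate",
    "median_estimate",
]

_KMEANS_RETRIES = 5


@dataclass(frozen=True)
class BaselineReport:
    """A baseline canopy-distance estimate (cm)."""

    method: str
    canopy_estimate: float
    centers: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.canopy_estimate) or self.canopy_estimate <= 0:
            raise ValueError("canopy estimate must be finite and positive")


def kmeans_estimate(
    samples: SampleSet, c: int, seed: int = 0
) -> BaselineReport:
    """Lloyd's k-means with seeded random-sample init; canopy = smallest center.

    An empty cluster triggers a reseed (up to a few retries) before failing,
    mirroring k-means' well-known sensitivity to its initial centers.
    """
    if samples.n < c:
        raise ValueError("need at least as many samples as clusters")
    last_err: Exception | None = None
    for attempt in range(_KMEANS_RETRIES):
        try:
            centers, _ = kmeans2(
                samples.values,
                c,
                minit="points",
                seed=np.random.default_rng((seed, attempt)),
                missing="raise",
            )
        except Exception as err:  # ClusterError: empty cluster
            last_err = err
            continue
        order = np.lexsort(centers.T[::-1])
        centers = centers[order]
        return BaselineReport(
            method="k-means",
            canopy_estimate=float(centers[0, 0]),
            centers=tuple(float(v) for v in centers[:, 0])
            if samples.d == 1
            else None,
        )
    raise RuntimeError(
        f"k-means produced an empty cluster in {_KMEANS_RETRIES} seeded tries"
    ) from last_err


def mean_estimate(samples: SampleSet) -> BaselineReport:
    """Arithmetic mean of the whole scan (biased toward deeper layers)."""
    return BaselineReport(
        method="mean", canopy_estimate=float(samples.values.mean())
    )


def median_estimate(samples: SampleSet) -> BaselineReport:
    """Sample median (mean of middle two for even n)."""
    return BaselineReport(
        method="median", canopy_estimate=float(np.median(samples.values))
    )
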