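"""Turn a clustered range scan into canopy / ground distances.

The cluster center closest to the sensor is the canopy; the farthest one is
the ground — but only if it is plausibly the ground.  On a dense canopy the
sound never reaches the soil, and the farthest cluster is just a deep leaf
layer, so the farthest center is accepted as ground only when it lies within
``ground_tol`` of the known sensor mounting height (``nominal_ground``).
Canopy height follows by subtraction: ground distance minus canopy distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isodata import ClusterModel

__all__ = ["CanopyResult", "extract_canopy_ground"]


@dataclass(frozen=True)
class CanopyResult:
    """Canopy/ground distances (cm) extracted from a cluster model."""

    canopy_distance: float
    ground_detected: bool
    ground_distance: float | None
    canopy_height: float | None
    nominal_ground: float
    ground_tol: float
    cluster_centers: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "canopy_distance_cm": self.canopy_distance,
            "ground_detected": self.ground_detected,
            "ground_distance_cm": self.ground_distance,
            "canopy_height_cm": self.canopy_height,
            "nominal_ground_cm": self.nominal_ground,
            "ground_tol_cm": self.ground_tol,
            "centers_cm": list(self.cluster_centers),
        }


def extract_canopy_ground(
    model: ClusterModel,
    nominal_ground: float = 81.0,
    ground_tol: float = 5.0,
) -> CanopyResult:
    """Extract sensor-to-canopy and (when plausible) sensor-to-ground distance.

    The smallest cluster center is always reported as the canopy distance; a
    rejected ground cluster does not affect it.  Raises ``ValueError`` for a
    single-cluster model, which cannot separate canopy from anything.
    """
    if nominal_ground <= 0.0:
        raise ValueError("nominal_ground must be positive")
    if ground_tol < 0.0:
        raise ValueError("ground_tol must be non-negative")
    if model.c < 2:
        raise ValueError("need at least 2 clusters to separate the canopy")
    centers = np.sort(model.center_values)
    canopy = float(centers[0])
    farthest = float(centers[-1])
    detected = abs(farthest - nominal_ground) <= ground_tol
    return CanopyResult(
        canopy_distance=canopy,
        ground_detected=detected,
        ground_distance=farthest if detected else None,
        canopy_height=(farthest - canopy) if detected else None,
        nominal_ground=nominal_ground,
        ground_tol=ground_tol,
        cluster_centers=tuple(float(v) for v in centers),
    )
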