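"""Synthetic ultrasonic range-scan generator with ground truth.

Emulates a bench rig: a downward-pointing ultrasonic sensor travels along a
rail over potted plants spaced at a fixed interval, logging one distance per
sampling tick.  Each plant presents a stack of echo layers — canopy on top,
zero to three lower-leaf layers, and (unless occluded) the soil at the known
mounting height.  Three stochastic features of real scans are modeled:

* per-sample Gaussian range jitter (``noise_sd``), generated by integrating
  a seeded fine-grained disturbance field over the sensor's dwell distance
  and normalizing to constant variance, so scans at different speeds under
  the same seed share one disturbance realization (paired comparisons);
* echo dropout (``dropout_prob``): an inclined leaf reflects the pulse away
  and the sensor reports the next deeper visible layer instead (or the
  maximum range, under the alternative ``"max-range"`` policy);
* sample counts shrinking with travel speed at a fixed sampling rate.

Every sample carries its true source layer, so estimator errors can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from numpy.typing import NDArray

from .extraction import extract_canopy_ground
from .fuzzy_core import SampleSet
from .isodata import IsodataConfig, run_fuzzy_isodata

__all__ = [
    "PlantProfile",
    "ScanScenario",
    "LabeledScan",
    "STAGE_PRESETS",
    "stage_scenario",
    "simulate_scan",
    "speed_sweep",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

#: resolution (cm) of the underlying disturbance field
_FIELD_CELL_CM = 0.05


@dataclass(frozen=True)
class PlantProfile:
    """Echo-layer stack of one plant.

    ``layer_widths[k]`` is the fraction of the plant footprint that returns
    layer k, where layer 0 is the canopy and layers 1.. are lower leaves in
    increasing distance.  Any remaining fraction returns the ground; a plant
    whose canopy fully occludes the soil has ``ground_visible=False`` and
    widths summing to one.
    """

    canopy_distance: float
    lower_leaf_distances: tuple[float, ...] = ()
    layer_widths: tuple[float, ...] = (0.5,)
    growth_stage_label: str = ""
    ground_visible: bool = True

    def __post_init__(self) -> None:
        leaves = tuple(float(v) for v in self.lower_leaf_distances)
        widths = tuple(float(w) for w in self.layer_widths)
        object.__setattr__(self, "lower_leaf_distances", leaves)
        object.__setattr__(self, "layer_widths", widths)
        if len(leaves) > 3:
            raise ValueError("at most 3 lower-leaf layers are supported")
        stack = (self.canopy_distance,) + leaves
        if any(b <= a for a, b in zip(stack, stack[1:])):
            raise ValueError(
                "layer distances must increase strictly from the canopy down"
            )
        if len(widths) != len(stack):
            raise ValueError("need one width per layer (canopy + leaves)")
        if any(w <= 0 for w in widths):
            raise ValueError("layer widths must be positive")
        total = sum(widths)
        if total > 1.0 + 1e-9:
            raise ValueError("layer widths must sum to at most 1")
        if not self.ground_visible and abs(total - 1.0) > 1e-9:
            raise ValueError(
                "an occluding plant's layer widths must sum to 1"
            )

    @property
    def layer_distances(self) -> tuple[float, ...]:
        return (self.canopy_distance,) + self.lower_leaf_distances


#: Stage presets for potted corn.  Layer distances (cm from the sensor) are
#: the per-stage echo-layer locations; visible fractions shrink for deeper
#: layers as the growing canopy occludes them, and the soil disappears
#: entirely at the 6-leaf stage.
STAGE_PRESETS: dict[str, PlantProfile] = {
    "3-leaf": PlantProfile(
        canopy_distance=63.25,
        lower_leaf_distances=(),
        layer_widths=(0.50,),
        growth_stage_label="3-leaf",
        ground_visible=True,
    ),
    "4-leaf": PlantProfile(
        canopy_distance=59.81,
        lower_leaf_distances=(65.53,),
        layer_widths=(0.45, 0.25),
        growth_stage_label="4-leaf",
        ground_visible=True,
    ),
    "5-leaf": PlantProfile(
        canopy_distance=44.26,
        lower_leaf_distances=(51.21, 66.14),
        layer_widths=(0.35, 0.25, 0.20),
        growth_stage_label="5-leaf",
        ground_visible=True,
    ),
    "6-leaf": PlantProfile(
        canopy_distance=39.71,
        lower_leaf_distances=(43.19, 46.87, 66.46),
        layer_widths=(0.34, 0.26, 0.22, 0.18),
        growth_stage_label="6-leaf",
        ground_visible=False,
    ),
}


@dataclass(frozen=True)
class ScanScenario:
    """One bench run: plants under the rail plus sensing conditions."""

    plants: tuple[PlantProfile, ...] = field(
        default_factory=lambda: (STAGE_PRESETS["4-leaf"],) * 5
    )
    nominal_ground: float = 81.0  # cm, sensor mounting height
    plant_spacing: float = 0.3  # m between pots
    speed_kmh: float = 1.0
    sample_rate_hz: float = 44.0
    noise_sd: float = 0.5  # cm
    dropout_prob: float = 0.05
    dropout_policy: str = "next-layer"  # or "max-range"
    max_range: float = 1100.0  # cm, sensor ceiling (max-range policy)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "plants", tuple(self.plants))
        if not self.plants:
            raise ValueError("scenario needs at least one plant")
        if not 0.0 < self.speed_kmh <= 10.0:
            raise ValueError("speed must lie in (0, 10] km/h")
        if self.sample_rate_hz <= 0.0:
            raise ValueError("sample rate must be positive")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")
        if self.dropout_policy not in ("next-layer", "max-range"):
            raise ValueError("dropout_policy must be next-layer or max-range")
        for p in self.plants:
            if any(d >= self.nominal_ground for d in p.layer_distances):
                raise ValueError(
                    "all plant layers must lie above the ground"
                )

    @property
    def track_length_cm(self) -> float:
        return len(self.plants) * self.plant_spacing * 100.0

    @property
    def truth_canopy(self) -> float:
        """True sensor-to-canopy distance (closest layer of any plant)."""
        return min(p.canopy_distance for p in self.plants)

    @property
    def truth_ground(self) -> float | None:
        if any(p.ground_visible for p in self.plants):
            return self.nominal_ground
        return None


@dataclass(frozen=True)
class LabeledScan:
    """A simulated scan with per-sample ground-truth labels."""

    positions_m: NDArray[np.float64]
    distances_cm: NDArray[np.float64]
    labels: tuple[str, ...]  # "dropout-filled" where the first echo was lost
    source_layers: tuple[str, ...]  # layer actually measured
    truth_canopy: float
    truth_ground: float | None
    scenario: ScanScenario

    @property
    def n(self) -> int:
        return self.distances_cm.shape[0]

    def samples(self) -> SampleSet:
        return SampleSet.from_distances(self.distances_cm)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_m": self.positions_m,
                "distance_cm": self.distances_cm,
                "label": list(self.labels),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def stage_scenario(stage: str, n_plants: int = 5, **overrides) -> ScanScenario:
    """Scenario with ``n_plants`` identical plants of a growth-stage preset."""
    if stage not in STAGE_PRESETS:
        raise KeyError(
            f"unknown stage {stage!r}; choose from {sorted(STAGE_PRESETS)}"
        )
    return ScanScenario(plants=(STAGE_PRESETS[stage],) * n_plants, **overrides)


def _layer_at(plant: PlantProfile, frac: float) -> int:
    """Layer index under footprint fraction ``frac``; -1 means ground."""
    cum = 0.0
    for k, w in enumerate(plant.layer_widths):
        cum += w
        if frac < cum:
            return k
    return -1


def _layer_name(k: int) -> str:
    if k == -1:
        return "ground"
    if k == 0:
        return "canopy"
    return f"leaf-{k}"


def simulate_scan(scenario: ScanScenario) -> LabeledScan:
    """Simulate one pass of the sensor along the rail.

    Deterministic for a fixed scenario seed.  The sample count is
    ``floor(track_length / (speed * sample_interval))``; a speed too high
    for the track (zero samples) raises ``ValueError``.
    """
    v_cm_s = scenario.speed_kmh * 100.0 / 3.6
    step_cm = v_cm_s / scenario.sample_rate_hz
    track_cm = scenario.track_length_cm
    n = int(np.floor(track_cm / step_cm))
    if n == 0:
        raise ValueError("speed too high for the track: zero samples")
    positions_cm = np.arange(n) * step_cm
    spacing_cm = scenario.plant_spacing * 100.0

    n_plants = len(scenario.plants)
    plant_idx = np.minimum(
        (positions_cm // spacing_cm).astype(int), n_plants - 1
    )
    fracs = (positions_cm % spacing_cm) / spacing_cm

    ss = np.random.SeedSequence(scenario.seed)
    rng_field, rng_drop = (np.random.default_rng(s) for s in ss.spawn(2))

    n_sub = max(1, int(round(step_cm / _FIELD_CELL_CM)))
    n_cells = int(np.ceil(track_cm / _FIELD_CELL_CM)) + n_sub + 2
    drop_field = rng_drop.random(n_cells)
    if scenario.noise_sd > 0.0:
        cells = rng_field.standard_normal(n_cells)
        csum = np.concatenate(([0.0], np.cumsum(cells)))
        a = (positions_cm / _FIELD_CELL_CM).astype(int)
        noise = (
            (csum[a + n_sub] - csum[a])
            / np.sqrt(n_sub)
            * scenario.noise_sd
        )
    else:
        noise = np.zeros(n)

    distances = np.empty(n)
    labels: list[str] = []
    sources: list[str] = []
    cell_at = (positions_cm / _FIELD_CELL_CM).astype(int)
    for i in range(n):
        plant = scenario.plants[plant_idx[i]]
        k = _layer_at(plant, fracs[i])
        dropped = (
            scenario.dropout_prob > 0.0
            and k != -1
            and drop_field[cell_at[i]] < scenario.dropout_prob
        )
        if dropped:
            if scenario.dropout_policy == "max-range":
                distances[i] = scenario.max_range
                labels.append("dropout-filled")
                sources.append("max-range")
                continue
            # next-layer policy: the first echo is lost and the next deeper
            # visible surface answers instead (deepest layer stays put).
            if k + 1 < len(plant.layer_widths):
                k = k + 1
            elif plant.ground_visible:
                k = -1
            label = "dropout-filled"
        else:
            label = _layer_name(k)
        base = (
            scenario.nominal_ground
            if k == -1
            else plant.layer_distances[k]
        )
        distances[i] = base + noise[i]
        labels.append(label)
        sources.append(_layer_name(k))

    return LabeledScan(
        positions_m=positions_cm / 100.0,
        distances_cm=distances,
        labels=tuple(labels),
        source_layers=tuple(sources),
        truth_canopy=scenario.truth_canopy,
        truth_ground=scenario.truth_ground,
        scenario=scenario,
    )


def speed_sweep(
    scenario_base: ScanScenario,
    speeds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 6.0),
    replicates: int = 20,
    config: IsodataConfig | None = None,
) -> pd.DataFrame:
    """Mean absolute canopy error of the clustering pipeline per speed.

    Each replicate draws a fresh scenario seed (derived from the base seed)
    shared across all speeds, so speeds are compared on one disturbance
    realization per replicate (common random numbers).  Returns a tidy
    frame: speed_kmh, mean_abs_error_cm, mean_samples.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if config is None:
        config = IsodataConfig()
    rep_seeds = [
        int(np.random.SeedSequence([scenario_base.seed, r]).generate_state(1)[0])
        % (2**31)
        for r in range(replicates)
    ]
    rows = []
    for v in speeds:
        errs = np.empty(replicates)
        sizes = np.empty(replicates)
        for r, s in enumerate(rep_seeds):
            scenario = replace(scenario_base, speed_kmh=v, seed=s)
            scan = simulate_scan(scenario)
            model = run_fuzzy_isodata(scan.samples(), config)
            result = extract_canopy_ground(
                model, nominal_ground=scenario.nominal_ground
            )
            errs[r] = abs(result.canopy_distance - scan.truth_canopy)
            sizes[r] = scan.n
        rows.append(
            {
                "speed_kmh": v,
                "mean_abs_error_cm": errs.mean(),
                "mean_samples": sizes.mean(),
            }
        )
    return pd.DataFrame(rows)


def _scenario_to_dict(scenario: ScanScenario) -> dict:
    return {
        "nominal_ground": scenario.nominal_ground,
        "plant_spacing": scenario.plant_spacing,
        "speed_kmh": scenario.speed_kmh,
        "sample_rate_hz": scenario.sample_rate_hz,
        "noise_sd": scenario.noise_sd,
        "dropout_prob": scenario.dropout_prob,
        "dropout_policy": scenario.dropout_policy,
        "max_range": scenario.max_range,
        "seed": scenario.seed,
        "plants": [
            {
                "canopy_distance": p.canopy_distance,
                "lower_leaf_distances": list(p.lower_leaf_distances),
                "layer_widths": list(p.layer_widths),
                "growth_stage_label": p.growth_stage_label,
                "ground_visible": p.ground_visible,
            }
            for p in scenario.plants
        ],
    }


def scenario_to_yaml(scenario: ScanScenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_scenario_to_dict(scenario), fh, sort_keys=False)


def scenario_from_yaml(path) -> ScanScenario:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    plants = tuple(
        PlantProfile(
            canopy_distance=p["canopy_distance"],
            lower_leaf_distances=tuple(p.get("lower_leaf_distances", ())),
            layer_widths=tuple(p["layer_widths"]),
            growth_stage_label=p.get("growth_stage_label", ""),
            ground_visible=p.get("ground_visible", True),
        )
        for p in raw.pop("plants")
    )
    return ScanScenario(plants=plants, **raw)
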