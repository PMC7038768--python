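# Methods

## Model and procedure

A scan is an ordered stream of sensor-to-surface distances (cm) from a
downward-pointing ultrasonic sensor traveling over crop plants. Echoes come
from a small number of distance layers (canopy, lower leaves, soil), so
canopy localization is cast as 1-D clustering with an unknown cluster count.

The pipeline is fuzzy ISODATA:

1. **Initialization.** `c_init` centers at evenly spaced quantiles
   `(2i+1)/(2c)` of the data (deterministic; a seeded random-sample init is
   available). The initial partition is the crisp nearest-center
   assignment. Two degenerate cases are handled explicitly: (a) if the
   quantiles collide (short scans with heavily repeated values), 1-D
   initialization falls back to quantiles of the *unique* sample values,
   which are strictly increasing and therefore distinct — exact duplicate
   centers are a frozen symmetry of the fuzzy updates (identical rows update
   identically forever) and would silently waste a cluster; (b) a center
   that would receive zero total membership is deleted with a logged event.
2. **Fuzzy c-means (inner loop).** Alternate the center update
   `V_i = Σ u_ij^q X_j / Σ u_ij^q` and the membership update
   `u_ij = 1 / Σ_p (d_ij²/d_pj²)^(1/(q−1))` (centers first) until
   `max|Δu| ≤ ε` or `max_inner` iterations. A sample coinciding with m
   centers takes membership 1/m on each (the limiting crisp convention). The
   objective `J(U,V) = Σ u_ij^q d_ij²` is non-increasing across iterations;
   non-convergence returns a flagged state with a warning rather than an
   exception.
3. **Hard assignment.** Nearest center, centers sorted ascending, ties to
   the lower index. Clusters emptied by reassignment are deleted (logged).
4. **Split.** Cluster i splits iff `σ_i > θ_S` **and** `D̄_i > D̄` **and**
   `n_i > 2(θ_n + 1)` (all strict), where `D̄_i` is the mean member-center
   distance, `D̄` its count-weighted global mean, and `σ_i` the population
   (divisor `n_i`) standard deviation. Replacement centers are exactly
   `V_i − 0.5σ_i` and `V_i + 0.5σ_i`; for d > 1 the displacement runs along
   the dominant axis of the within-cluster scatter (the scalar rule is only
   well-defined at d = 1, and all range data is d = 1).
5. **Merge.** Center pairs with distance `< θ_c` (strict) merge at the
   count-weighted mean `(n_i V_i + n_j V_j)/(n_i + n_j)`; candidate pairs
   are processed in ascending distance and each cluster joins at most one
   merge per round.
6. **Outer loop.** Steps 1–5 form a round; a split or merge invalidates the
   converged partition, so rounds repeat until one passes with no structural
   change, or `max_outer` is reached (then the converged model from the last
   round is returned and the unapplied proposals are logged; single-pass
   behavior is available via `max_outer = 1`).

Extraction reads the final sorted centers: the smallest is the canopy
distance; the largest is accepted as the ground only if within
`ground_tol` of the known mounting height `nominal_ground` — a dense canopy
blocks the soil echo, and the farthest cluster is then a deep leaf layer.
Rejecting the ground never affects the canopy estimate. Canopy height is
`ground − canopy` when the ground is detected.

Clustering quality is scored by partition entropy
`v_PE = −(1/n) Σ_j Σ_i u_ij ln u_ij` (natural log, `0·ln 0 ≡ 0`), bounded
by `[0, ln c]`; lower is better.

## Parameters

| name | meaning | default | why |
| --- | --- | --- | --- |
| `c_init` | initial cluster count | 3 | canopy / lower leaves / ground |
| `epsilon` | FCM convergence threshold | 1e−4 | partition stable to 4 decimals; keeps iteration counts small |
| `q` | fuzzy weight exponent | 2 | the standard choice for FCM |
| `theta_n` | minimum cluster population | 20 | split only clusters populous enough to yield two viable children |
| `theta_s` | split dispersion threshold (cm) | 5 | a single echo layer with sub-cm jitter never splits; two pooled layers ≳10 cm apart do |
| `theta_c` | minimum center separation (cm) | 2 | layers closer than 2 cm are not resolvable targets |
| `max_outer` | split/merge rounds | 10 | quiescence usually in 1–2 rounds |
| `max_inner` | FCM iteration cap | 300 | guardrail against non-convergence |
| `nominal_ground` | sensor mounting height (cm) | 81 | bench geometry |
| `ground_tol` | ground plausibility tolerance (cm) | 5 | matches the accuracy considered acceptable for boom control |

## Synthetic scans

`scan_sim` emulates a bench rig: plants at 0.3 m spacing under a rail, the
sensor sampling at 44 Hz while traveling at 0.5–6 km/h. The sample count is
`floor(track / (speed · Δt))`, so doubling the speed halves the data — at
6 km/h a five-plant scan yields ≈ 40 samples. Each plant is a stack of echo
layers (canopy, 0–3 lower-leaf layers, optionally the soil), each occupying
a fixed fraction of the plant footprint. Growth-stage presets place the
layers at the per-stage distances listed above in the clustering examples
(3-leaf: canopy 63.25 + ground; 4-leaf: 59.81/65.53 + ground; 5-leaf:
44.26/51.21/66.14 + ground; 6-leaf: 39.71/43.19/46.87/66.46, ground fully
occluded), with visible fractions shrinking for deeper layers and the
ground share vanishing at the 6-leaf stage.

Stochastic effects:

* **Range jitter.** Per-sample Gaussian noise (default sd 0.5 cm, typical
  of cm-class ultrasonic ranging). It is generated by integrating a seeded
  fine-grained (0.05 cm) white disturbance field over the sensor's dwell
  distance and normalizing to constant variance, so each scan's noise is
  exactly iid N(0, sd²) while scans at different speeds under one seed
  share a single disturbance realization. Speed comparisons are thereby
  paired (common random numbers), which is why the error-versus-speed trend
  is estimated with low variance.
* **Echo dropout.** With probability 0.05 an inclined leaf reflects the
  pulse away and the sensor reports the next deeper visible layer (the
  deepest layer stays put); an alternative `max-range` policy returns the
  sensor ceiling instead.

What the generator does **not** model: the 10° beam cone (a point footprint
is used, so no mixing of adjacent layers inside the cone), temperature /
humidity / wind effects on the speed of sound, boom vibration, and
continuous within-layer leaf-surface relief — each echo layer is a single
distance. Passing tests therefore show that the algorithm recovers layered
structure under realistic sample counts, jitter and dropout; they do not
show robustness to beam-cone mixing or to layers that are themselves broad.

## Experiment design choices

* **Structure recovery across stages** initializes at the maximum plausible
  layer count (`c_init = 4`) and lets merging/deletion prune surplus
  centers. Starting *below* the true layer count cannot always be repaired
  by splitting: with delta-valued layers, a c = 3 solution pools the two
  nearest layers, and when those are only ~3.5 cm apart the pooled
  dispersion (~1.8 cm) never exceeds `theta_s = 5`. (With `c_init = 3` the
  5-leaf stage is still fully recovered — its pooled pair spans ~15 cm, the
  split fires, and all four centers land exactly — but the 6-leaf stage
  stalls at 3 clusters.) Initializing high and pruning is the standard
  ISODATA remedy and is what the structure experiment documents.
* **Speed sweep**: five speeds {0.5, 1, 2, 4, 6} km/h, 20 replicates,
  4-leaf plants, default noise and dropout; each replicate derives one seed
  shared across speeds (paired comparison, above).
* **Layer-recovery fixtures**: three Gaussian layers at 60/66/80 cm,
  sd 0.5 cm, 100–150 points per layer, 20 seeded replicates; recovery means
  every center within 1 cm.
* Problem sizes throughout (hundreds of samples per scan, tens of
  replicates) match the bench conditions being emulated and keep the whole
  suite fast.

## Numerical notes

* Membership columns with a vanishing (or float-underflowed) distance are
  assigned uniformly over the minimal-distance centers.
* A cluster whose total membership weight underflows to zero raises a
  degenerate-cluster error naming the cluster.
* Split centers are emitted with the exact float expression `V ± 0.5σ`;
  merge centers with the exact weighted-mean expression.
* Hard-assignment ties (a sample exactly midway) go to the lower cluster
  index after ascending-center sort.
* All reported center lists are sorted ascending; the partition rows are
  permuted accordingly, so memberships, labels and centers always agree.

## Known limitations

* Layers closer than `theta_c` are by construction unresolvable, and layers
  closer than ~`2 theta_s` cannot be separated by splitting if ever pooled.
* The ground plausibility rule is an absolute tolerance around a known
  mounting height; on a sprayer whose boom height varies, `nominal_ground`
  must track the boom position.
* d > 1 inputs are accepted by the core (Euclidean norms, scatter-axis
  splits) but the extraction step and simulator are strictly 1-D.
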