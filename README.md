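# canopyscan

Crop canopy localization from ultrasonic range scans, via **fuzzy ISODATA**
clustering.

## The problem

Boom sprayers need to hold their nozzles at a constant distance above the
crop canopy. A downward-pointing ultrasonic sensor riding on the boom
returns a stream of distances, but that stream mixes echoes from the canopy,
from lower leaf layers, and from the soil — so neither the raw readings nor
simple summaries (mean, median) give the sensor-to-canopy distance. The
echoes do, however, separate cleanly into distance *layers*. `canopyscan`
clusters the 1-D range stream, adapts the number of clusters to however many
layers the scan actually contains, and reports:

* **canopy distance** — the cluster center closest to the sensor;
* **ground distance** — the farthest center, accepted only if it lies within
  a tolerance of the known mounting height (a dense canopy blocks the soil
  echo, and then the farthest cluster is just a deep leaf layer);
* **canopy height** — ground distance minus canopy distance.

The package is aimed at agricultural-sensing practitioners: it ships the
clustering library, a synthetic bench-scan simulator with per-sample ground
truth, baseline estimators, and a small CLI.

## The method

Samples `X = {X_1..X_n}` (distances, cm) are clustered by fuzzy c-means:
minimize

```
J(U, V) = Σ_i Σ_j u_ij^q ‖X_j − V_i‖²,   Σ_i u_ij = 1,  u_ij ∈ [0, 1]
```

by alternating the stationarity updates (weight exponent `q = 2`):

```
V_i = Σ_j u_ij^q X_j / Σ_j u_ij^q
u_ij = 1 / Σ_p (‖X_j − V_i‖² / ‖X_j − V_p‖²)^(1/(q−1))
```

until `max |u_ij^(k+1) − u_ij^(k)| ≤ ε`. Around that inner loop, ISODATA
moves adjust the cluster count: a cluster with standard deviation
`σ_i > θ_S`, above-average mean member distance, and population
`n_i > 2(θ_n + 1)` is **split** into centers `V_i ± 0.5 σ_i`; center pairs
closer than `θ_c` are **merged** at their count-weighted mean. Rounds repeat
until no structural change. Clustering quality is scored by the partition
entropy `v_PE(U) = −(1/n) Σ_j Σ_i u_ij ln u_ij` (0 = crisp, ln c = maximally
uncertain). Defaults: `c_init = 3`, `ε = 1e−4`, `θ_n = 20`, `θ_S = 5` cm,
`θ_c = 2` cm.

## Worked example

Simulate a bench scan of five 4-leaf corn plants (sensor 81 cm above the
soil, 1 km/h, default noise), then cluster it:

```
$ canopyscan simulate --stage 4-leaf --speed 1 --seed 42 --out scan.csv
wrote 237 samples to scan.csv (truth canopy 59.81 cm)

$ canopyscan cluster scan.csv --seed 0
{
  "n_samples": 237,
  "canopy_distance_cm": 59.84049006078406,
  "ground_detected": true,
  "ground_distance_cm": 81.0462140913568,
  "canopy_height_cm": 21.20572403057274,
  "centers_cm": [59.84049006078406, 65.51444370896033, 81.0462140913568],
  "v_pe": 0.03286648472806077,
  ...
}
```

Three layers were found: canopy at 59.84 cm (true value 59.81 — the scan's
plants present their canopy there), a lower-leaf layer at 65.51 cm, and the
ground at 81.05 cm, accepted because it sits within 5 cm of the 81 cm
mounting height; canopy height follows by subtraction (21.2 cm). The tiny
partition entropy (0.033 versus ln 3 ≈ 1.1) says the memberships are almost
crisp — the layers are well separated.

Compare against the baselines on the same scan:

```
$ canopyscan compare scan.csv --truth 59.81 --seed 0
method,canopy_cm,abs_error_cm
fuzzy-isodata,59.8405,0.0305
k-means,59.8429,0.0329
mean,67.7746,7.9646
median,65.1863,5.3763
```

The whole-scan mean and median are pulled several centimeters toward the
lower leaves and the ground; the clustering estimators are within a
third of a millimeter of the truth here, and unlike k-means, fuzzy ISODATA
needs no externally supplied cluster count and is far less sensitive to
initialization.

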