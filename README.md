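# myrmeco

Semi-automated monitoring of **seed dispersal by ants** (myrmecochory) in
large laboratory arenas, from raw time-lapse imagery to spatial statistics
and mechanistic simulation.

Ants collect elaiosome-bearing diaspores, eat the elaiosome in the nest and
reject the bare seed into the arena — and often pick it up again later
(redispersal). Observing this requires detecting millimetre-scale seeds over
square metres of floor and telling them apart from similarly dark,
similarly sized but *moving* ants. This package implements the full
measurement chain:

1. **Stitching** (`myrmeco.stitching`) — two overlapping camera views are
   registered with a homography estimated from checkerboard correspondence
   points (normalised DLT + least squares), exposure-equalised by shifting
   each image's mean luminance to the global mean, and composited along a
   hard *stitch line* with no blending, so no seed can appear twice or
   blurred. A radial lens-distortion model (r′ = r(1 + k₁r² + k₂r⁴)) can be
   applied/inverted.
2. **Detection** (`myrmeco.detection`) — a static background is built per
   pixel as the modal RGB triplet over frames; pixels whose RGB distance to
   it exceeds a threshold and which are dark enough are foreground; a
   temporal **persistence filter** keeps pixels present in ≥ 2 of 3
   consecutive frames (seeds persist, walking ants do not); connected
   components of 5–19 px (at 0.677 mm/px) are seeds, larger persistent blobs
   are static ants, non-persistent blobs are ants with no size gate.
3. **Platform** (`myrmeco.platform`) — diaspores remaining on the foraging
   platform (dark blobs minus ant-sized blobs inside a polygon) and the
   in/out flow of ants as directed crossings of a gate segment by tracked
   trajectories.
4. **Tracking** (`myrmeco.tracking`) — per-frame seed detections are linked
   into occupancy *episodes*; from these come rejection dynamics, episode
   durations λ = (frames observed) × Δt, and minimum redispersal distances
   (nearest episode opening within 2 frames of a closure).
5. **Spatial statistics** (`myrmeco.spatial`, `myrmeco.circular`) — the
   nearest-neighbour G-function G(d), pointwise envelopes from 1000 fixed-n
   CSR simulations, the one-sided DCLF test with exact rank p-value
   p = rank/(n_sim+1), characteristic clustering/CSR distances
   (NNdist_cluster, NNdist_CSR), radial density profiles, and four circular
   uniformity tests (Rayleigh, Kuiper, Watson, Rao spacing).
6. **Simulator** (`myrmeco.simulate`) — isotropic centrifugal seed dropping
   with **blind** carriers (drop at a drawn target distance) or **reactive**
   carriers (drop early on encountering a previously dropped seed within a
   5 mm perception range), classified clustered/CSR with the same machinery.
7. **Synthetic scenes** (`myrmeco.synthetic`) — ground-truthed renders of
   arena frames (noisy floor, 1–2.5 mm seeds, 4–6 mm moving ants, two-view
   split with known homography and per-camera exposure offsets) so every
   stage is testable without external data.

## Worked example

Render 3 random two-camera layouts of 58 seeds (noise σ = 5 grey levels,
±10 grey-level camera offsets), run the full pipeline, then simulate and
classify a reactive dispersal pattern:

```python
from myrmeco.benchmarks import seed_detection_rate
from myrmeco.simulate import DispersalConfig, simulate_dispersal
from myrmeco.spatial import (PointPattern, area_of_interest,
                             characteristic_distances, dclf_test,
                             distance_summary, envelope)

print(f"detection rate: {seed_detection_rate(n_layouts=3, seed=7):.1f}%")

out = simulate_dispersal(DispersalConfig(model="reactive", n_seeds=200,
                                         rng_seed=7))
aoi = area_of_interest(out.pattern.region, 5.0)
pts = out.pattern.points[aoi.contains(out.pattern.points)]
env = envelope(PointPattern(pts, aoi), n_sim=999, rng=7)
res = dclf_test(env)
cd = characteristic_distances(env, res)
med, q1, q3 = distance_summary(PointPattern(pts, aoi))
print(f"verdict={res.verdict} U={res.u_obs:.3g} rank={res.rank} p={res.p:.3f}")
print(f"NNdist_cluster median = {cd.nndist_cluster[0]:.1f} cm, "
      f"NNdist_CSR median = {cd.nndist_csr[0]:.1f} cm")
print(f"distance to nest: {med:.1f} [{q1:.1f}; {q3:.1f}] cm")
```

prints

```
detection rate: 100.0%
verdict=clustered U=0.39 rank=1 p=0.001
NNdist_cluster median = 4.5 cm, NNdist_CSR median = 8.7 cm
distance to nest: 131.1 [84.7; 165.4] cm
```

The detection rate is the fraction of ground-truth seeds recovered by the
pipeline. The reactive simulation produces a pattern whose G-curve is the
most extreme among 999 CSR simulations (rank 1, p = 1/1000), i.e. clustered;
the seeds in the clustered fraction sit markedly closer to each other
(median 4.5 cm) than the same fraction would under randomness (8.7 cm).

A command-line interface mirrors the library:
`myrmeco synth | stitch | detect | platform | track | stats | simulate`
(see `myrmeco --help`).

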