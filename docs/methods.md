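# Methods

This note documents the models, conventions and design decisions behind
`myrmeco`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Imaging model and stitching

Frames are 8-bit RGB grids with a physical resolution (default
0.677 mm/pixel) and a timestamp in minutes. Two fixed cameras view the
arena with an overlap; their geometric relation is a plane projective
transformation (homography), valid because the arena floor is planar.

**Luminosity compensation** is an *additive* offset on the luminance
channel (L = mean(R, G, B)), applied equally to all channels and clipped to
[0, 255], shifting every image's mean luminance to the global mean of the
batch. Additive compensation is exposure-like, preserves within-image
contrast ordering exactly, and is reversible away from clipping; a
multiplicative model would change contrast and interact with the darkness
threshold. After compensation each image's mean luminance is within 0.5
grey level (quantisation) of the global mean unless clipping intervenes.

**Homography estimation** uses the normalised (Hartley) direct linear
transform on ≥ 4 correspondence pairs; with > 4 pairs the algebraic
solution is refined by Levenberg–Marquardt on the summed squared
reprojection error. Configurations with fewer than 4 pairs, or with enough
collinearity to drop the design matrix below rank 8, are rejected. On
noise-free correspondences the matrix is recovered to relative error
≤ 1e-6; at 0.2 px coordinate noise the mean reprojection error stays below
0.5 px (both are tested).

**Undistortion** applies the radial model r_corrected = r(1 + k₁r² + k₂r⁴)
in focal-length units around the principal point; the inverse radius is
found by Newton iteration (8 steps, initialised at the target radius), and
images are resampled with bilinear interpolation (nearest available for
bit-exact tests). Output dimensions equal input dimensions. Measuring k₁,
k₂ from calibration photographs is out of scope; the model is applied, not
fitted.

**Stitching** composites the two views over the joint bounding box of
image A's corners and image B's warped corners, origin at the box top-left,
pixel coordinates 0-based with x rightward and y downward. Every composite
pixel is copied verbatim from exactly one source; within the overlap the
source is chosen by the side of a *stitch line*, by default the
perpendicular bisector of the two image centres, configurable as any
polyline (side = sign of the cross product with the nearest segment).
No blending means no ghosting: a seed in the overlap appears exactly once.

## Detection

* **Background**: per-pixel modal RGB triplet over ≥ 2 frames; ties break
  to the lexicographically smallest triplet (deterministic). Regions can be
  overwritten manually (`manual_patches`), mirroring the manual removal of
  seed/ant traces from real backgrounds. In practice the background should
  be built from frames of the empty arena: static seeds present in most
  frames would otherwise enter the mode.
* **Segmentation**: foreground where the Euclidean RGB distance to the
  background strictly exceeds `diff_threshold` (default 40 grey levels),
  then restricted to dark pixels, luminance ≤ `dark_threshold` (default
  90). The defaults suit dark seeds/ants on a light floor with noise
  σ ≈ 5; both are configurable and the benchmarks pin behaviour through
  rendered scenes rather than through these specific values.
* **Persistence**: a pixel survives if present in ≥ 2 of 3 consecutive
  masks, aligned to the middle frame. The window slides by one frame; the
  first and last frames of a sequence therefore yield no seed detections.
* **Blobs**: maximal connected components, 8-connectivity by default
  (seeds are compact), with size and arithmetic-mean centroid.
* **Classification**: persistent blobs within the published 5–19 px gate
  are seeds; persistent blobs outside it are discarded as static ants;
  blobs of the per-frame mask minus the persistent mask are ants, with no
  size threshold. Reading "moving = segmented minus persistent" is the
  natural complement of "seeds persist, ants move". Centroids are converted
  to arena centimetres relative to the nest centre, with the y axis negated
  so arena y points up.

## Tracking

Episodes link seed detections across frames by greedy nearest-neighbour
matching within `match_radius_px` (default 3 px ≈ 2 mm: resting seeds are
static, anything farther is a redispersal, not jitter). An episode's
position is the running mean of its detections; it closes at the first
frame with no match. Durations use λ = (last − first + 1) × Δt: a seed
seen in n consecutive frames at Δt = 10 min has λ = 10 n min, so the
minimal 2-frame episode gives 20 min. Overnight observation gaps are
detected from timestamps (consecutive observations > 1.5 Δt apart);
episodes spanning a gap are flagged and excluded from duration summaries by
default, since their apparent duration includes unobserved hours.
Redispersal distances take, for each closing episode, the nearest episode
opening within the following 2 frames; episodes with no candidate get NaN,
never zero.

## Spatial statistics

The observation window is shrunk by a 5 cm border buffer (seeds pile up
against the arena wall) and only points inside the buffered window are
analysed and simulated. G(d) is the empirical CDF of nearest-neighbour
distances on a 512-point grid from 0 to the window diameter, with **no edge
correction**: observed and simulated patterns use the identical estimator,
so the CSR comparison is unbiased even though the estimator itself is not.
CSR is simulated as a *binomial* process (exactly n uniform points — the
same number of seeds as observed), not a Poisson-count process.

The envelope is the pointwise min/max (rank-1) band over `n_sim`
simulations. Note the distinction between pointwise and global coverage: at
any fixed distance the observed CSR curve leaves the band with probability
≈ 2/(n_sim+1), but the probability of leaving it *somewhere* along the
curve is much larger (measured ≈ 35% at n = 100, n_sim = 99). Significance
is therefore never read off the envelope; it comes from the DCLF test.

The DCLF statistic is u = ∫₀^dmax dev(d)² dd (trapezoidal), where dev is
the deviation of G from the simulation mean rectified to the one-sided
alternative (positive part for "clustered"). Each simulated curve receives
the same statistic against the mean of the *other* simulations; the exact
Monte-Carlo p-value is p = rank/(n_sim+1) with rank = 1 + #{u_sim > u_obs},
so the most extreme observation among 1000 simulations reports rank 1,
p = 1/1001 ≈ 0.001. d_max defaults to the 95th percentile of the pooled
simulated NN distances (the informative range of G; the integral above it
is constant). Calibration and power are tested: empirical size at α = 0.05
is within [0.03, 0.08] over 400 CSR trials, and ≥ 95% of Thomas-cluster
patterns (20 parents × 10 offspring, σ = 3 cm, 195 cm disc) are declared
clustered.

When a pattern is clustered, f\* is the largest observed G value over the
distances where G exceeds the upper envelope; NNdist_cluster summarises
(median [Q1; Q3], type-7 quantiles throughout) the observed NN distances at
or below the f\*-quantile of the observed NN distances, and NNdist_CSR
applies each simulation's own f\*-quantile to its NN distances, pooled.
"The fraction of NN distances above the envelope" admits more than one
construction; this one is used consistently for observed and simulated
patterns.

Circular uniformity uses four tests on seed bearings. Rayleigh reports
R̄ and the classical series p ≈ e^{-Z}(1 + (2Z − Z²)/4n), Z = nR̄².
Kuiper and Watson use Stephens' modified statistics against the standard
critical points at α ∈ {0.10, 0.05, 0.01} (verdict bands, as is
conventional for these tables). Rao's spacing statistic
U = ½Σ|Tᵢ − 2π/n| has no closed-form null; rather than embed printed
tables of limited coverage, the null distribution is generated once per
sample size by Monte Carlo (1999 samples, fixed internal seed, cached) and
an exact rank p-value is reported — deterministic, reproducible, and
calibrated (≤ 10% rejections on uniform samples at α = 0.05, tested).

## Dispersal simulator

Carriers act sequentially. Each leaves the nest (origin) at a heading
uniform on [0, 2π), walks straight outward in steps of 0.25 cm toward a
target distance drawn from the drop-distance law, and drops its seed at the
target (blind) or at the first step where a previously dropped seed lies
within the perception range (reactive, default 0.5 cm; the step never
exceeds the perception range, so a perception disc cannot be stepped over).
With perception 0 the reactive model reproduces the blind model draw for
draw. Patterns are classified with the same buffered-window envelope + DCLF
machinery as experimental data.

The default drop-distance law is **area-uniform** (r = R√u): blind dropping
is then exactly CSR, its clustered fraction sits at the test's α, and the
median drop distance R/√2 ≈ 141 cm (R = 200 cm) matches the observed
median seed distance. A truncated-exponential law is available but note
that it concentrates carriers near the nest (areal density ∝ e^{−r/μ}/r),
which registers as clustering even for blind dropping — a property of the
law, not of the dropping rule. Under the defaults, blind runs classify
clustered in ≈ 8% of 50 runs and reactive (5 mm) runs in ≈ 100%,
reproducing the qualitative contrast between the two mechanisms; the
clustered fraction is monotone in the perception range. Redispersal is
deliberately absent from the simulator.

## Synthetic scenes

The renderer emulates: a light floor (mean 200) with i.i.d. Gaussian pixel
noise (default σ = 5 grey levels); seeds as anti-aliased dark discs
(luminance 30) of width 1–2.5 mm; ants as dark 4–6 mm ellipses (luminance
40, aspect ≈ 4:1) performing a bounded random walk of ≥ 1.5 body lengths
per frame that also avoids its own position two frames back, other ants'
adjacent-frame positions, and resting seeds — so ant pixels can never
satisfy the 2-of-3 persistence rule; a two-view mode splitting the frame
into two overlapping views (30% overlap, known translation homography)
with per-camera luminance offsets (default ±10 grey levels); and
appear/disappear schedules driving rejection/redispersal fixtures.
Rendering is deterministic given the scene seed.

**Seed rasterisation.** At 0.677 mm/px an ideal 1 mm disc covers < 2
pixels, yet real 1–2.5 mm seeds segment to 5–19 px — soft edges, shadows
and demosaicing spread a seed's dark footprint well beyond its geometric
area. The renderer encodes this empirical mapping with an inflated drawn
radius, r_px = 1.38 + 0.39 · width_mm, calibrated so that segmented blob
sizes across the full width range and noise levels fall in 7–17 px —
inside the published gate with margin on both sides. The mapping is
empirical, not disc geometry, and is asserted by tests.

**What the benchmarks show.** Scenes have uniform floors, ideal optics
(the two-view homography is a translation), Gaussian noise and perfectly
static seeds. They validate the algorithmic chain — stitching without
doubling, exposure compensation, persistence-based discrimination, size
gating, episode linking — under controlled degradation (noise, exposure
offsets). They do not emulate blotting-paper texture, shadows, ant
excretion stains (the known false-positive source in real data), partial
occlusions, or lens blur; real-data detection rates therefore need the
manual spot checks the workflow provides (`D_count`, `S_count_end`).

**Benchmark sizes.** The standard detection benchmark uses 20 layouts of
58 seeds in a 20 cm-radius rendered arena (591² px frames) with 5
empty-arena composites for the background and 3 scene frames; the
discrimination benchmark uses 10 sequences × 7 frames × 4 ants (40 ants,
50 persistence triplets). These sizes give stable percentages while keeping
the full benchmark suite around a minute of CPU.

## Numerical conventions

Quantiles are numpy type-7 (linear interpolation) everywhere. Modal-RGB
ties break lexicographically. Strict inequality at the difference
threshold; inclusive at the darkness threshold and the size gate. Blob
connectivity defaults to 8. All Monte-Carlo entry points take an explicit
seed (default 0) and are bit-reproducible; batch runs derive per-run
generators from `numpy.random.SeedSequence.spawn`.

## Known limitations

* Ant *identity* is not tracked across frames, and seed identity is not
  preserved through a redispersal (the minimum-distance proxy is computed
  instead, as in the original workflow).
* The composite's absolute dimensions depend on camera geometry; only the
  bounding-box construction is reproduced, not any particular pixel count.
* The DCLF verdict under the one-sided "upper" alternative never reports
  "regular"; run with `alternative="lower"` to test for regularity.
* `PolygonRegion` sampling is by rejection from the bounding box — fine
  for convex-ish windows, slow for extremely thin ones.
* Kuiper/Watson verdicts are table-banded at α ∈ {0.10, 0.05, 0.01}
  rather than continuous p-values.
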