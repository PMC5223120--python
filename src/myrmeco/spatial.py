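"""Spatial point-pattern statistics for rejected-seed maps.

The spatial question is whether seeds rejected from the nest form clusters
or are spread at random.  The toolkit is the classical nearest-neighbour
G-function compared against Monte-Carlo envelopes of complete spatial
randomness (CSR):

* ``g_function`` — empirical cumulative distribution of nearest-neighbour
  distances, with no edge correction: instead the observation window is
  shrunk by a border buffer (``area_of_interest``) and the identical
  estimator is applied to observed and simulated patterns alike, so the
  comparison is unbiased;
* ``envelope`` — pointwise min/max band of the G-function over ``n_sim``
  fixed-n CSR simulations (binomial process: the same number of points as
  observed, uniform on the region);
* ``dclf_test`` — Diggle–Cressie–Loosmore–Ford goodness-of-fit test on the
  integrated squared (one-sided) deviation of G from the simulation mean,
  with the exact rank-based p-value p = rank / (n_sim + 1);
* ``characteristic_distances`` — summaries of the nearest-neighbour
  distances in the clustered fraction (the part of the G-curve above the
  envelope) and of the same fraction under CSR;
* ``radial_density`` — seed density in 10 cm concentric rings around the
  nest;
* ``distance_summary`` — quartiles of seed distances to the nest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely import contains_xy as _shp_contains_xy
from shapely.geometry import Polygon as _ShpPolygon


@dataclass
class DiscRegion:
    """A disc observation window (cm), centred on ``centre``."""

    centre: tuple[float, float] = (0.0, 0.0)
    radius: float = 195.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be positive")

    @property
    def area(self) -> float:
        return float(np.pi * self.radius**2)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        d = np.hypot(pts[:, 0] - self.centre[0], pts[:, 1] - self.centre[1])
        return d <= self.radius + 1e-9

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r = self.radius * np.sqrt(rng.random(n))
        theta = rng.random(n) * 2 * np.pi
        return np.column_stack(
            [self.centre[0] + r * np.cos(theta), self.centre[1] + r * np.sin(theta)]
        )


@dataclass
class PolygonRegion:
    """A simple-polygon observation window (cm)."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self._poly = _ShpPolygon(np.asarray(self.vertices, dtype=np.float64))
        if not self._poly.is_valid:
            raise ValueError("polygon region is not simple/valid")

    @property
    def area(self) -> float:
        return float(self._poly.area)

    @property
    def diameter(self) -> float:
        xmin, ymin, xmax, ymax = self._poly.bounds
        return float(np.hypot(xmax - xmin, ymax - ymin))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return _shp_contains_xy(self._poly.buffer(1e-9), pts[:, 0], pts[:, 1])

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        xmin, ymin, xmax, ymax = self._poly.bounds
        out = np.empty((0, 2))
        while len(out) < n:
            m = max(2 * (n - len(out)), 16)
            cand = np.column_stack(
                [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
            )
            out = np.vstack([out, cand[self.contains(cand)]])
        return out[:n]


@dataclass
class PointPattern:
    """Points (cm) inside an observation region."""

    points: np.ndarray
    region: DiscRegion | PolygonRegion

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(pts) and not self.region.contains(pts).all():
            raise ValueError("all points must lie inside the region")
        self.points = pts

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class GCurve:
    """Empirical cumulative fraction of NN distances, on a distance grid."""

    d_grid: np.ndarray
    values: np.ndarray


@dataclass
class EnvelopeResult:
    d_grid: np.ndarray
    observed: GCurve
    sim_mean: GCurve
    lo: np.ndarray
    hi: np.ndarray
    n_sim: int
    sim_curves: np.ndarray  # (n_sim, len(d_grid))
    sim_nn_distances: np.ndarray  # (n_sim, n) per-simulation NN distances
    observed_nn: np.ndarray


@dataclass
class DCLFResult:
    u_obs: float
    rank: int
    p: float
    verdict: str  # clustered | CSR | regular
    d_max: float
    sim_u: np.ndarray = field(repr=False, default=None)


@dataclass
class ClusterDistances:
    f_star: float
    nndist_cluster: tuple[float, float, float] | None  # median, Q1, Q3
    nndist_csr: tuple[float, float, float] | None
    n_cluster: int = 0
    n_csr: int = 0


def area_of_interest(region: DiscRegion, buffer_cm: float = 5.0) -> DiscRegion:
    """Shrink a disc window by a border buffer (default 5 cm).

    Seeds piling up against the arena wall would bias the pattern analysis;
    only the portion of the arena at least ``buffer_cm`` from the border is
    analysed.
    """
    if buffer_cm < 0:
        raise ValueError("buffer must be nonnegative")
    if buffer_cm >= region.radius:
        raise ValueError("buffer must be smaller than the region radius")
    return DiscRegion(centre=region.centre, radius=region.radius - buffer_cm)


def nn_distances(pattern: PointPattern) -> np.ndarray:
    """Distance from each point to its nearest other point."""
    if pattern.n < 2:
        raise ValueError("need >= 2 points")
    tree = cKDTree(pattern.points)
    d, _ = tree.query(pattern.points, k=2)
    return d[:, 1]


def default_d_grid(region: DiscRegion | PolygonRegion, m: int = 512) -> np.ndarray:
    return np.linspace(0.0, region.diameter, m)


def _g_values(nn: np.ndarray, d_grid: np.ndarray) -> np.ndarray:
    s = np.sort(nn)
    return np.searchsorted(s, d_grid, side="right") / len(s)


def g_function(pattern: PointPattern, d_grid: np.ndarray | None = None) -> GCurve:
    """G(d) = fraction of nearest-neighbour distances <= d (no edge correction)."""
    if d_grid is None:
        d_grid = default_d_grid(pattern.region)
    nn = nn_distances(pattern)
    return GCurve(d_grid=np.asarray(d_grid, dtype=np.float64), values=_g_values(nn, d_grid))


def simulate_csr(
    n: int,
    region: DiscRegion | PolygonRegion,
    rng: np.random.Generator | int | None = 0,
) -> PointPattern:
    """Fixed-n CSR: exactly n independent uniform points on the region.

    A binomial process (conditioned point count) rather than a Poisson count
    is used so that every simulation has *the same number of seeds* as the
    observed pattern.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return PointPattern(points=region.sample(n, rng), region=region)


def envelope(
    pattern: PointPattern,
    n_sim: int = 1000,
    rng: np.random.Generator | int | None = 0,
    d_grid: np.ndarray | None = None,
) -> EnvelopeResult:
    """Pointwise min/max envelope of G over ``n_sim`` CSR simulations."""
    if pattern.n < 2:
        raise ValueError("need >= 2 points")
    if n_sim < 1:
        raise ValueError("need >= 1 simulation")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if d_grid is None:
        d_grid = default_d_grid(pattern.region)
    d_grid = np.asarray(d_grid, dtype=np.float64)
    obs_nn = nn_distances(pattern)
    obs = GCurve(d_grid, _g_values(obs_nn, d_grid))
    sim_nn = np.empty((n_sim, pattern.n))
    sim_curves = np.empty((n_sim, len(d_grid)))
    for i in range(n_sim):
        sim = simulate_csr(pattern.n, pattern.region, rng)
        sim_nn[i] = nn_distances(sim)
        sim_curves[i] = _g_values(sim_nn[i], d_grid)
    return EnvelopeResult(
        d_grid=d_grid,
        observed=obs,
        sim_mean=GCurve(d_grid, sim_curves.mean(axis=0)),
        lo=sim_curves.min(axis=0),
        hi=sim_curves.max(axis=0),
        n_sim=n_sim,
        sim_curves=sim_curves,
        sim_nn_distances=sim_nn,
        observed_nn=obs_nn,
    )


def _one_sided_u(
    dev: np.ndarray, d: np.ndarray, alternative: str
) -> float | np.ndarray:
    if alternative == "upper":
        dev = np.maximum(dev, 0.0)
    elif alternative == "lower":
        dev = np.maximum(-dev, 0.0)
    elif alternative != "two-sided":
        raise ValueError("alternative must be upper, lower or two-sided")
    sq = dev**2
    if sq.ndim == 1:
        return float(np.trapezoid(sq, d))
    return np.trapezoid(sq, d, axis=-1)


def dclf_test(
    env: EnvelopeResult,
    alternative: str = "upper",
    d_max: float | None = None,
    alpha: float = 0.05,
) -> DCLFResult:
    """Diggle–Cressie–Loosmore–Ford goodness-of-fit test.

    The statistic is u = ∫₀^d_max dev(d)² dd (trapezoidal), where dev is the
    deviation of the G-curve from the simulation mean, rectified according to
    the one-sided alternative ("upper" detects clustering).  Each simulated
    curve gets the same statistic computed against the mean of the *other*
    simulations; rank = 1 + #{simulated u > u_obs} and p = rank / (n_sim+1),
    so the most extreme observation among 1000 simulations has rank 1 and
    p = 1/1001 ≈ 0.001.

    ``d_max`` defaults to the 95th percentile of the pooled simulated NN
    distances.
    """
    d = env.d_grid
    if d_max is None:
        d_max = float(np.quantile(env.sim_nn_distances, 0.95))
    if not (d[0] <= d_max <= d[-1]) or d_max <= d[0]:
        raise ValueError("d_max outside the distance grid")
    sel = d <= d_max
    dg = d[sel]
    obs_dev = env.observed.values[sel] - env.sim_mean.values[sel]
    u_obs = _one_sided_u(obs_dev, dg, alternative)
    S = env.sim_curves[:, sel]
    total = S.sum(axis=0)
    if env.n_sim > 1:
        mean_others = (total[None, :] - S) / (env.n_sim - 1)
    else:
        mean_others = S
    sim_u = _one_sided_u(S - mean_others, dg, alternative)
    rank = 1 + int(np.sum(sim_u > u_obs))
    p = rank / (env.n_sim + 1)
    if p <= alpha and u_obs > 0:
        verdict = "clustered" if alternative == "upper" else (
            "regular" if alternative == "lower" else "non-CSR"
        )
    else:
        verdict = "CSR"
    return DCLFResult(
        u_obs=float(u_obs), rank=rank, p=p, verdict=verdict, d_max=d_max, sim_u=sim_u
    )


def characteristic_distances(
    env: EnvelopeResult, dclf: DCLFResult
) -> ClusterDistances:
    """Characteristic clustering and CSR nearest-neighbour distances.

    f* is the largest value of the observed G-curve over the distances at
    which it exceeds the upper envelope; the clustered fraction is then the
    observed NN distances at or below the f*-quantile of the observed NN
    distances, and the CSR counterpart applies each simulation's own
    f*-quantile to its NN distances, pooled over simulations.  Summaries are
    median [Q1; Q3] (type-7 quantiles).
    """
    if dclf.verdict != "clustered":
        return ClusterDistances(f_star=0.0, nndist_cluster=None, nndist_csr=None)
    above = env.observed.values > env.hi
    if not above.any():
        return ClusterDistances(f_star=0.0, nndist_cluster=None, nndist_csr=None)
    f_star = float(env.observed.values[above].max())
    obs_nn = env.observed_nn
    thr = np.quantile(obs_nn, f_star)
    cluster = obs_nn[obs_nn <= thr]
    pooled = []
    for row in env.sim_nn_distances:
        t = np.quantile(row, f_star)
        pooled.append(row[row <= t])
    csr = np.concatenate(pooled) if pooled else np.empty(0)

    def _summ(x: np.ndarray) -> tuple[float, float, float] | None:
        if len(x) == 0:
            return None
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        return (float(med), float(q1), float(q3))

    return ClusterDistances(
        f_star=f_star,
        nndist_cluster=_summ(cluster),
        nndist_csr=_summ(csr),
        n_cluster=len(cluster),
        n_csr=len(csr),
    )


def radial_density(
    pattern: PointPattern, ring_width_cm: float = 10.0
) -> list[tuple[int, float, float, int, float]]:
    """Seed density in concentric rings around the nest (region centre).

    Ring k covers [k·w, (k+1)·w) (half-open).  For a disc region centred on
    the nest, the outermost ring is clipped to the disc so the density uses
    the actually observable area.  Returns (k, inner, outer, count, density)
    tuples, density in points per cm².
    """
    if not ring_width_cm > 0:
        raise ValueError("ring width must be positive")
    centre = (
        np.asarray(pattern.region.centre)
        if isinstance(pattern.region, DiscRegion)
        else np.zeros(2)
    )
    if isinstance(pattern.region, DiscRegion):
        r_max = pattern.region.radius
    else:
        r_max = pattern.region.diameter / 2.0
    n_rings = int(np.ceil(r_max / ring_width_cm))
    if pattern.n:
        d = np.hypot(
            pattern.points[:, 0] - centre[0], pattern.points[:, 1] - centre[1]
        )
    else:
        d = np.empty(0)
    out = []
    for k in range(n_rings):
        inner = k * ring_width_cm
        outer = (k + 1) * ring_width_cm
        count = int(np.sum((d >= inner) & (d < outer)))
        outer_eff = min(outer, r_max) if isinstance(pattern.region, DiscRegion) else outer
        area = np.pi * (outer_eff**2 - inner**2)
        out.append((k, inner, outer, count, count / area if area > 0 else 0.0))
    return out


def distance_summary(pattern: PointPattern) -> tuple[float, float, float]:
    """Median [Q1; Q3] of point distances to the origin (nest centre)."""
    if pattern.n < 1:
        raise ValueError("empty pattern")
    d = np.hypot(pattern.points[:, 0], pattern.points[:, 1])
    q1, med, q3 = np.quantile(d, [0.25, 0.5, 0.75])
    return (float(med), float(q1), float(q3))


def simulate_thomas(
    n_parents: int,
    n_offspring: int,
    sigma_cm: float,
    region: DiscRegion,
    rng: np.random.Generator | int | None = 0,
) -> PointPattern:
    """Thomas cluster process with a fixed number of parents and offspring.

    Parents are uniform on the region; each parent gets ``n_offspring``
    children displaced by isotropic Gaussian noise with scale ``sigma_cm``.
    Children falling outside the region are resampled from their parent.
    Used as a known-clustered reference pattern in power studies.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    parents = region.sample(n_parents, rng)
    pts = []
    for p in parents:
        placed = 0
        while placed < n_offspring:
            c = p + rng.normal(scale=sigma_cm, size=(n_offspring - placed, 2))
            c = c[region.contains(c)]
            pts.append(c)
            placed += len(c)
    return PointPattern(points=np.vstack(pts), region=region)
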