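"""Seed occupancy episodes: rejection dynamics and redispersal metrics.

A rejected seed occupies one spot in the arena for a contiguous run of
frames before an ant picks it up again (redispersal).  Per-frame seed
detections are linked into *episodes* — one seed at one location over a
contiguous frame interval — from which we derive:

* rejection dynamics: the number of seeds present per frame, optionally as a
  fraction of the manual end-of-experiment count;
* episode durations before redispersal (λ = frames observed × Δt);
* minimum redispersal distances: for each episode that ends, the distance to
  the nearest episode opening within the following two frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .detection import FrameDetections


@dataclass
class SeedEpisode:
    """One seed occupying one location over a contiguous frame interval."""

    episode_id: int
    position_cm: tuple[float, float]
    position_px: tuple[float, float]
    first_frame: int
    last_frame: int
    first_ts: float
    last_ts: float
    duration_min: float
    distance_to_nest_cm: float
    gap: bool = False
    redisp_dist_cm: float = math.nan  # NaN marks "no candidate" (undefined)

    def __post_init__(self) -> None:
        if self.last_frame < self.first_frame:
            raise ValueError("episode ends before it starts")


@dataclass
class RejectionSeries:
    """Per-frame count of seeds present in the arena."""

    frames: np.ndarray
    counts: np.ndarray
    s_track_end: int
    s_count_end: int | None = None
    eta_rejected: np.ndarray | None = None


class _OpenEpisode:
    __slots__ = ("eid", "sum_px", "sum_cm", "n", "first_frame", "last_frame",
                 "first_ts", "last_ts", "gap")

    def __init__(self, eid: int, px, cm, frame: int, ts: float) -> None:
        self.eid = eid
        self.sum_px = np.asarray(px, dtype=np.float64).copy()
        self.sum_cm = np.asarray(cm, dtype=np.float64).copy()
        self.n = 1
        self.first_frame = self.last_frame = frame
        self.first_ts = self.last_ts = ts
        self.gap = False

    @property
    def mean_px(self) -> np.ndarray:
        return self.sum_px / self.n

    @property
    def mean_cm(self) -> np.ndarray:
        return self.sum_cm / self.n

    def extend(self, px, cm, frame: int, ts: float, dt: float) -> None:
        if ts - self.last_ts > 1.5 * dt:
            self.gap = True
        self.sum_px += px
        self.sum_cm += cm
        self.n += 1
        self.last_frame = frame
        self.last_ts = ts

    def close(self, dt: float) -> SeedEpisode:
        cm = self.mean_cm
        return SeedEpisode(
            episode_id=self.eid,
            position_cm=(float(cm[0]), float(cm[1])),
            position_px=tuple(self.mean_px),
            first_frame=self.first_frame,
            last_frame=self.last_frame,
            first_ts=self.first_ts,
            last_ts=self.last_ts,
            duration_min=(self.last_frame - self.first_frame + 1) * dt,
            distance_to_nest_cm=float(np.hypot(cm[0], cm[1])),
            gap=self.gap,
        )


def link_episodes(
    detections: list[FrameDetections],
    match_radius_px: float = 3.0,
    dt: float = 10.0,
) -> list[SeedEpisode]:
    """Greedy nearest-neighbour linking of seed detections into episodes.

    A seed detected within ``match_radius_px`` of an open episode's running
    mean position continues that episode; otherwise a new episode opens.  An
    episode closes at the first frame with no match.  Matching is greedy by
    ascending distance, so each detection joins at most one episode and each
    episode absorbs at most one detection per frame.

    The default radius, 3 px (~2 mm at 0.677 mm/px), reflects that resting
    seeds are static: any larger displacement is a redispersal, not jitter.
    """
    ts = [d.timestamp for d in detections]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("detections must be ordered by strictly increasing time")
    open_eps: list[_OpenEpisode] = []
    closed: list[SeedEpisode] = []
    next_id = 0
    for frame_idx, det in enumerate(detections):
        seeds = det.seeds
        matched_eps: set[int] = set()
        matched_seeds: set[int] = set()
        if open_eps and seeds:
            ep_pos = np.array([e.mean_px for e in open_eps])
            seed_pos = np.array([s.centroid_px for s in seeds])
            dmat = cdist(seed_pos, ep_pos)
            pairs = np.argwhere(dmat <= match_radius_px)
            order = np.argsort(dmat[pairs[:, 0], pairs[:, 1]], kind="stable")
            for si, ei in pairs[order]:
                if si in matched_seeds or ei in matched_eps:
                    continue
                matched_seeds.add(int(si))
                matched_eps.add(int(ei))
                open_eps[ei].extend(
                    np.asarray(seeds[si].centroid_px),
                    np.asarray(seeds[si].centroid_cm),
                    frame_idx,
                    det.timestamp,
                    dt,
                )
        still_open = []
        for ei, ep in enumerate(open_eps):
            if ei in matched_eps:
                still_open.append(ep)
            else:
                closed.append(ep.close(dt))
        open_eps = still_open
        for si, seed in enumerate(seeds):
            if si not in matched_seeds:
                open_eps.append(
                    _OpenEpisode(
                        next_id,
                        np.asarray(seed.centroid_px),
                        np.asarray(seed.centroid_cm),
                        frame_idx,
                        det.timestamp,
                    )
                )
                next_id += 1
    closed.extend(ep.close(dt) for ep in open_eps)
    closed.sort(key=lambda e: e.episode_id)
    return closed


def redispersal_distances(
    episodes: list[SeedEpisode],
    window_frames: int = 2,
    final_frame: int | None = None,
) -> list[tuple[SeedEpisode, float]]:
    """Minimum redispersal distance for each episode that closes.

    For an episode ending at frame t, the candidates are episodes opening in
    frames t+1 .. t+window_frames; the reported distance is the Euclidean
    distance (cm) to the nearest candidate.  Episodes with no candidate get
    NaN (undefined — never zero-filled).  Episodes still open at
    ``final_frame`` (default: the last frame seen) did not close and are not
    reported.  The distances are also written onto ``redisp_dist_cm``.
    """
    if not episodes:
        return []
    if final_frame is None:
        final_frame = max(e.last_frame for e in episodes)
    out = []
    for ep in episodes:
        if ep.last_frame >= final_frame:
            continue
        cands = [
            o
            for o in episodes
            if ep.last_frame + 1 <= o.first_frame <= ep.last_frame + window_frames
        ]
        if cands:
            p = np.asarray(ep.position_cm)
            dist = min(float(np.hypot(*(np.asarray(o.position_cm) - p))) for o in cands)
        else:
            dist = math.nan
        ep.redisp_dist_cm = dist
        out.append((ep, dist))
    return out


def rejection_dynamics(
    episodes: list[SeedEpisode],
    frame_range: tuple[int, int],
    s_count_end: int | None = None,
) -> RejectionSeries:
    """Per-frame count of open episodes over ``frame_range`` (inclusive).

    When the manual end count ``s_count_end`` is given, the rejected fraction
    η(t) = count(t) / s_count_end is attached.
    """
    lo, hi = frame_range
    frames = np.arange(lo, hi + 1)
    counts = np.zeros(len(frames), dtype=np.int64)
    for ep in episodes:
        a = max(ep.first_frame, lo)
        b = min(ep.last_frame, hi)
        if a <= b:
            counts[a - lo : b - lo + 1] += 1
    s_track_end = int(counts[-1]) if len(counts) else 0
    eta = None
    if s_count_end is not None:
        if s_count_end == 0:
            raise ValueError("s_count_end must be positive to compute η")
        eta = counts / s_count_end
    return RejectionSeries(
        frames=frames,
        counts=counts,
        s_track_end=s_track_end,
        s_count_end=s_count_end,
        eta_rejected=eta,
    )


def duration_stats(
    episodes: list[SeedEpisode], include_gap: bool = False
) -> tuple[float, float, float]:
    """Median [Q1; Q3] of episode durations (minutes).

    Episodes spanning the overnight observation gap are excluded by default:
    their apparent duration includes unobserved hours.
    """
    durs = [e.duration_min for e in episodes if include_gap or not e.gap]
    if not durs:
        raise ValueError("no episodes to summarise")
    q1, med, q3 = np.quantile(durs, [0.25, 0.5, 0.75])
    return (float(med), float(q1), float(q3))
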