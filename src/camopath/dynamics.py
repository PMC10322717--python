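"""Trajectory dynamics in pattern / chromatophore space.

Speed of pattern change, transition-chunk detection, slow points (local
speed minima) with dwell phases, step and dwell statistics against distance
to the goal pattern, the update-vs-memory heading-angle contrast with its
Rayleigh test, correlation-to-background progress, motion/background epoch
bookkeeping, and pattern-change duration.

Conventions: speed sample ``i`` sits at the midpoint between frames ``i`` and
``i+1``; smoothing is a centered moving average that excludes invalid frames
and marks the result invalid (NaN) where more than half the window is
missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .core import FeatureTrajectory, SlowPointAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "SpeedProfile",
    "HeadingAngles",
    "pattern_speed",
    "detect_transitions",
    "find_slow_points",
    "step_statistics",
    "heading_angles",
    "rayleigh_test",
    "classify_heading_model",
    "background_correlation_progress",
    "detect_epochs",
    "change_duration",
]

#: Number of PCs used for speed, after the standard analysis choice.
SPEED_N_PCS = 200
#: Smoothing window for speed profiles, seconds.
SPEED_SMOOTH_S = 2.0
#: Distance bin (feature-space units) for step/dwell statistics.
DISTANCE_BIN = 55.0


@dataclass
class SpeedProfile:
    """Pattern-change speed: length T-1, aligned to inter-frame midpoints."""

    times: np.ndarray
    values: np.ndarray
    n_pcs: int
    smooth_window: float
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        valid = self.values[~np.isnan(self.values)]
        if valid.size and valid.min() < -1e-9:
            raise ValueError("speed must be non-negative")


@dataclass
class HeadingAngles:
    """Exit angles at slow points, radians in (-pi, pi].

    ``alpha``: exit direction vs direction-to-goal from the previous point
    (the update model predicts alpha concentrated at 0). ``beta``: exit
    direction vs the fixed start-to-goal direction (the memory model predicts
    beta concentrated at 0).
    """

    alpha: np.ndarray
    beta: np.ndarray


def _smooth_with_gaps(x: np.ndarray, win: int) -> np.ndarray:
    """Centered Gaussian smoothing (sigma = win/4, truncated at the window);
    NaNs excluded via normalized convolution, NaN out where >50% of the
    kernel mass is missing.

    A Gaussian (scale-space) kernel is used rather than a boxcar so that
    widening the window can only remove local speed minima, never create
    them — the property slow-point counting relies on.
    """
    sigma = win / 4.0
    half = max(int(np.ceil(2 * sigma)), 1)
    t = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    ok = ~np.isnan(x)
    num = np.convolve(np.where(ok, x, 0.0), kernel, mode="same")
    den = np.convolve(ok.astype(float), kernel, mode="same")
    out = np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)
    out[den < 0.5] = np.nan
    return out


def pattern_speed(
    traj: FeatureTrajectory,
    n_pcs: int = SPEED_N_PCS,
    smooth: float = SPEED_SMOOTH_S,
    valid_mask: np.ndarray | None = None,
) -> SpeedProfile:
    """Speed of pattern change: ``||x(t+dt) - x(t)|| / dt`` in the top
    ``n_pcs`` dimensions, then moving-average smoothed over ``smooth``
    seconds. Invalid frames propagate as gaps (NaN)."""
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames for a speed profile")
    d = min(n_pcs, traj.n_dims)
    if d < n_pcs:
        logger.info("pattern_speed: using all %d available dims (< n_pcs=%d)", d, n_pcs)
    dt = 1.0 / traj.rate
    coords = traj.coords[:, :d]
    raw = np.linalg.norm(np.diff(coords, axis=0), axis=1) / dt
    if valid_mask is not None:
        vm = np.asarray(valid_mask, dtype=bool)
        raw[~(vm[:-1] & vm[1:])] = np.nan
    win = max(int(round(smooth * traj.rate)), 1)
    smoothed = _smooth_with_gaps(raw, win) if win > 1 else raw
    times = (np.arange(raw.size) + 0.5) / traj.rate
    return SpeedProfile(times, smoothed, n_pcs=d, smooth_window=smooth, rate=traj.rate)


def detect_transitions(
    traj: FeatureTrajectory,
    subsample: int = 1,
    kmeans_k: int = 3,
    speed_sd_thresh: float = 1.0,
    merge_gap_s: float = 20.0,
    switch_frames: np.ndarray | None = None,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Transition chunks: frames where the k-means cluster label jumps or the
    speed of pattern change exceeds mean + ``speed_sd_thresh`` s.d.

    Each candidate grows to the surrounding interval where speed stays above
    the whole-recording mean (the baseline); chunks closer than
    ``merge_gap_s`` merge unless separated by a background-switch marker.
    Returns inclusive (start, end) frame pairs; an empty list is valid.
    """
    if not 2 <= kmeans_k <= 4:
        raise ValueError("kmeans_k must be between 2 and 4")
    sub = traj.coords[::subsample]
    labels = KMeans(n_clusters=kmeans_k, n_init=10, random_state=seed).fit_predict(sub)
    sp = pattern_speed(traj)
    speed = sp.values
    finite = np.nan_to_num(speed, nan=0.0)
    mean, sd = np.nanmean(speed), np.nanstd(speed)
    candidates = set()
    jumps = np.flatnonzero(np.diff(labels) != 0)
    for j in jumps:
        candidates.add(min(j * subsample, speed.size - 1))
    candidates.update(np.flatnonzero(finite > mean + speed_sd_thresh * sd).tolist())
    above = finite > mean
    chunks: list[tuple[int, int]] = []
    for c in sorted(candidates):
        if not above[c]:
            lo = hi = int(c)
        else:
            lo = int(c)
            while lo > 0 and above[lo - 1]:
                lo -= 1
            hi = int(c)
            while hi < above.size - 1 and above[hi + 1]:
                hi += 1
        if chunks and lo <= chunks[-1][1]:
            chunks[-1] = (chunks[-1][0], max(chunks[-1][1], hi))
        else:
            chunks.append((lo, hi))
    # merge over short gaps without an intervening background switch
    gap_frames = merge_gap_s * traj.rate
    switches = np.asarray(switch_frames) if switch_frames is not None else np.array([])
    merged: list[tuple[int, int]] = []
    for ch in chunks:
        if merged:
            prev = merged[-1]
            gap = ch[0] - prev[1]
            has_switch = np.any((switches > prev[1]) & (switches < ch[0]))
            if gap < gap_frames and not has_switch:
                merged[-1] = (prev[0], ch[1])
                continue
        merged.append(ch)
    return merged


def find_slow_points(speed: SpeedProfile, quartile: float = 25.0) -> SlowPointAnnotation:
    """Slow points: interior local minima of the smoothed speed profile.

    Around each minimum, the deceleration (preceding maximum to minimum) and
    acceleration (minimum to following maximum) segment is split into fast
    and slow by the segment's speed quartile (values below the 25th
    percentile are slow); the dwell interval is the contiguous slow run
    containing the minimum. Monotone profiles yield zero slow points.
    """
    v = np.asarray(speed.values, dtype=float)
    if v.size < 5:
        raise ValueError("speed profile too short")
    filled = np.where(np.isnan(v), np.nanmax(v) if np.isfinite(np.nanmax(v)) else 0.0, v)
    minima, props = find_peaks(-filled, plateau_size=1)
    # plateau minima: use the plateau midpoint
    if minima.size and "left_edges" in props:
        minima = ((props["left_edges"] + props["right_edges"]) // 2).astype(int)
    maxima, _ = find_peaks(filled, plateau_size=1)
    indices, intervals, thresholds = [], [], []
    phase_mask = np.zeros(v.size, dtype=bool)
    for m in minima:
        prev_max = maxima[maxima < m]
        next_max = maxima[maxima > m]
        lo = int(prev_max[-1]) if prev_max.size else 0
        hi = int(next_max[0]) if next_max.size else v.size - 1
        seg = filled[lo: hi + 1]
        thr = np.percentile(seg, quartile)
        slow = filled <= thr
        a = m
        while a > lo and slow[a - 1]:
            a -= 1
        b = m
        while b < hi and slow[b + 1]:
            b += 1
        indices.append(int(m))
        intervals.append((int(a), int(b)))
        thresholds.append(float(thr))
        phase_mask[a: b + 1] = True
    return SlowPointAnnotation(
        np.asarray(indices, dtype=int),
        intervals,
        phase_mask,
        float(np.mean(thresholds)) if thresholds else float("nan"),
    )


def step_statistics(
    traj: FeatureTrajectory,
    slow: SlowPointAnnotation,
    goal: np.ndarray,
    bin_width: float = DISTANCE_BIN,
) -> dict:
    """Steps and dwell time against distance to the goal in the top two PCs.

    Each slow point contributes one step at its distance-to-goal; the
    histogram counts steps per distance bin, and dwell times are bin-averaged
    along the same axis.
    """
    if slow.n_points < 1:
        raise ValueError("need at least one slow point")
    goal2 = np.asarray(goal, dtype=float)[:2]
    pts = traj.coords[slow.indices, :2]
    dist = np.linalg.norm(pts - goal2, axis=1)
    dwell = slow.dwell_times(traj.rate)
    n_bins = int(np.floor(dist.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(dist, bins=edges)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    dwell_mean = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            dwell_mean[b] = dwell[sel].mean()
    return {
        "bin_edges": edges,
        "step_counts": counts,
        "dwell_mean": dwell_mean,
        "distances": dist,
        "dwell_times": dwell,
    }


def _signed_angle(v: np.ndarray, w: np.ndarray) -> float:
    """Signed angle from w to v in the plane, atan2(cross, dot), in (-pi, pi]."""
    return float(np.arctan2(v[0] * w[1] - v[1] * w[0], v @ w))


def heading_angles(
    traj: FeatureTrajectory,
    slow: SlowPointAnnotation,
    start: np.ndarray | None = None,
    goal: np.ndarray | None = None,
) -> HeadingAngles:
    """Exit angles alpha and beta at each step between slow points.

    Points are the start followed by the trajectory at each slow point, in
    the top two PCs. For step ``n`` the exit vector is ``p(n) - p(n-1)``;
    alpha measures it against the direction to the goal from ``p(n-1)``, beta
    against the fixed start-to-goal direction. Zero-length exit vectors are
    skipped and logged. The goal defaults to the trajectory's final frame
    (the stabilized pattern); the start defaults to the first frame.
    """
    start2 = (traj.coords[0] if start is None else np.asarray(start, float))[:2]
    goal2 = (traj.coords[-1] if goal is None else np.asarray(goal, float))[:2]
    pts = np.vstack([start2, traj.coords[slow.indices, :2]])
    base = goal2 - start2
    alphas, betas = [], []
    for n in range(1, pts.shape[0]):
        v = pts[n] - pts[n - 1]
        if np.linalg.norm(v) < 1e-12:
            logger.info("heading_angles: zero-length exit vector at step %d skipped", n)
            continue
        to_goal = goal2 - pts[n - 1]
        if np.linalg.norm(to_goal) < 1e-12:
            continue
        alphas.append(_signed_angle(v, to_goal))
        betas.append(_signed_angle(v, base))
    return HeadingAngles(np.asarray(alphas), np.asarray(betas))


def rayleigh_test(angles: np.ndarray) -> tuple[float, float, float]:
    """Rayleigh test of circular uniformity: (mean resultant length, z, p).

    ``z = n * Rbar**2``; p follows the standard series approximation
    (clipped to [0, 1], where it can otherwise degenerate at large z).
    """
    theta = np.asarray(angles, dtype=float)
    n = theta.size
    if n < 5:
        raise ValueError("Rayleigh test needs at least 5 angles")
    rbar = float(np.abs(np.exp(1j * theta).mean()))
    z = n * rbar**2
    p = np.exp(-z) * (
        1
        + (2 * z - z**2) / (4 * n)
        - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
    )
    return rbar, float(z), float(np.clip(p, 0.0, 1.0))


def classify_heading_model(angles: HeadingAngles, level: float = 0.01) -> str:
    """Decide between the update and memory heading rules for one trajectory.

    Both rules predict alpha (exit vs direction-to-goal) concentrated at 0;
    only the memory rule also predicts beta (exit vs start-to-goal)
    concentrated. A trajectory is therefore classified ``update`` when the
    Rayleigh test does NOT reject uniformity of beta at ``level``, and
    ``memory`` when it does.
    """
    _, _, p_beta = rayleigh_test(angles.beta)
    return "update" if p_beta > level else "memory"


def background_correlation_progress(
    traj: FeatureTrajectory,
    slow: SlowPointAnnotation,
    bg_feature: np.ndarray,
    n_pcs: int = 50,
) -> np.ndarray:
    """Change in skin-to-background correlation after each step.

    Pearson correlation between the pattern state at each slow point and the
    background feature vector over the first ``n_pcs`` dimensions, minus the
    value at behaviour onset (frame 0).
    """
    d = min(n_pcs, traj.n_dims, np.asarray(bg_feature).size)
    bg = np.asarray(bg_feature, dtype=float)[:d]
    if np.std(bg) < 1e-15:
        raise ValueError("background feature vector is constant; correlation undefined")

    def corr(x: np.ndarray) -> float:
        if np.std(x) < 1e-15:
            raise ValueError("constant pattern state; correlation undefined")
        return float(np.corrcoef(x, bg)[0, 1])

    r_onset = corr(traj.coords[0, :d])
    return np.array([corr(traj.coords[i, :d]) - r_onset for i in slow.indices])


def detect_epochs(
    mask_centroids: np.ndarray,
    frame_corr: np.ndarray,
    rate: float = 25.0,
    min_period_s: float = 10.0,
    corr_thresh: float = 0.9,
    speed_sd: float = 2.0,
    patch_features: np.ndarray | None = None,
    k_backgrounds: int = 3,
    seed: int = 0,
) -> dict:
    """Constant-background periods, motion epochs within them and background
    identities.

    Constant-background periods are runs where the frame-to-frame image
    correlation stays above ``corr_thresh`` for at least ``min_period_s``.
    Motion epochs are frames (inside those periods) where the centroid speed
    exceeds its mean by ``speed_sd`` standard deviations. Identities come
    from seeded k-means (k=3) on pooled per-period patch features.
    """
    corr = np.asarray(frame_corr, dtype=float)
    cent = np.asarray(mask_centroids, dtype=float)
    if cent.shape[0] != corr.size + 1:
        raise ValueError("frame_corr must have length T-1 for T centroids")
    above = corr > corr_thresh
    edges = np.flatnonzero(np.diff(np.r_[False, above, False]))
    periods = []
    for i in range(0, edges.size, 2):
        lo, hi = int(edges[i]), int(edges[i + 1] - 1)
        if (hi - lo + 1) / rate >= min_period_s:
            periods.append((lo, hi + 1))  # frame range, inclusive
    speed = np.linalg.norm(np.diff(cent, axis=0), axis=1) * rate
    thr = speed.mean() + speed_sd * speed.std()
    motion = []
    for lo, hi in periods:
        seg = np.flatnonzero(speed[lo:hi] > thr) + lo
        if seg.size:
            splits = np.split(seg, np.flatnonzero(np.diff(seg) > 1) + 1)
            motion.extend((int(s[0]), int(s[-1])) for s in splits)
    identities = None
    if patch_features is not None and periods:
        feats = np.asarray(patch_features, dtype=float)
        k = min(k_backgrounds, feats.shape[0])
        identities = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(feats)
    return {"periods": periods, "motion_epochs": motion, "background_ids": identities}


def change_duration(
    speed: SpeedProfile,
    baseline: float | None = None,
    baseline_window_s: float = 10.0,
    frac: float = 0.10,
    mode: str = "span",
) -> dict:
    """Onset/offset of a pattern change from its speed profile.

    Threshold = baseline + ``frac`` x (peak - baseline); onset is the first
    upward crossing, offset the last downward crossing (linear interpolation
    between samples). ``baseline`` defaults to the mean speed over the first
    ``baseline_window_s`` seconds. ``mode='span'`` reports one event from
    first onset to last offset; ``mode='per-pulse'`` reports each
    above-threshold pulse separately.
    """
    v = np.asarray(speed.values, dtype=float)
    t = speed.times
    ok = ~np.isnan(v)
    if baseline is None:
        pre = ok & (t <= baseline_window_s)
        baseline = float(v[pre].mean()) if pre.any() else float(np.nanmin(v))
    peak = float(np.nanmax(v))
    if peak <= baseline:
        raise ValueError("no event: flat profile (no peak above baseline)")
    thr = baseline + frac * (peak - baseline)
    above = np.where(ok, v > thr, False)
    edges = np.flatnonzero(np.diff(above.astype(int)))
    events = []
    i = 0
    if above[0]:
        events.append([t[0], None])
        # first edge will be a fall
    for e in edges:
        if not above[e]:  # rising edge between e and e+1
            tc = t[e] + (thr - v[e]) / (v[e + 1] - v[e]) * (t[e + 1] - t[e])
            events.append([tc, None])
        else:  # falling edge
            tc = t[e] + (thr - v[e]) / (v[e + 1] - v[e]) * (t[e + 1] - t[e])
            if events and events[-1][1] is None:
                events[-1][1] = tc
    if events and events[-1][1] is None:
        events[-1][1] = float(t[-1])
    if not events:
        raise ValueError("no event: speed never crosses threshold")
    if mode == "per-pulse":
        return {
            "events": [(a, b, b - a) for a, b in events],
            "threshold": thr,
            "baseline": baseline,
        }
    onset, offset = events[0][0], events[-1][1]
    return {
        "onset": float(onset),
        "offset": float(offset),
        "duration": float(offset - onset),
        "threshold": thr,
        "baseline": baseline,
    }
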