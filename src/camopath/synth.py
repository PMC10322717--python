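"""Synthetic chromatophore scenes, area time series, trajectories and stimuli.

Every generator is a pure function of its parameters and a seed, and exports
enough ground truth to score the downstream stage it feeds (component labels,
slow-point frames, recruitment onsets, spectral exponents). Defaults emulate
the acquisition conditions of the real system: 25 frames/s sampling and a mean
chromatophore footprint of 54 pixels.

The generators emulate the statistical structure the analysis assumes — they
are not photorealistic skin renderings (no papillae, no light-chromatophore
classes, no lighting model).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal.windows import hann

from .core import (
    AreaMatrix,
    DEFAULT_RATE,
    FeatureTrajectory,
    LoomingStimulus,
    SceneTruth,
    TrajectoryTruth,
)

__all__ = [
    "gen_scene",
    "gen_component_timeseries",
    "gen_transition_trajectory",
    "gen_background",
    "gen_looming",
    "gen_blanch_trial",
    "render_frames",
]

#: Mean chromatophore footprint in pixels at acquisition resolution.
MEAN_AREA_PX = 54.0


# ------------------------------------------------------------------- scenes


def gen_scene(
    n_chrom: int,
    image_size: tuple[int, int] = (256, 256),
    mean_area_px: float = MEAN_AREA_PX,
    k_components: int = 1,
    seed: int = 0,
    layout: str = "patches",
    area_cv: float = 0.2,
    margin_px: float = 3.0,
) -> SceneTruth:
    """Place ``n_chrom`` non-overlapping discs with mean area ``mean_area_px``.

    Component labels are either spatially coherent (``layout='patches'``,
    contiguous groups found by position clustering) or ``'interdigitated'``
    (random assignment). Raises if the requested density is infeasible after
    bounded rejection sampling.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if k_components < 1 or k_components > n_chrom:
        raise ValueError("k_components must be in [1, n_chrom]")
    rng = np.random.default_rng(seed)
    H, W = image_size
    # Gamma-distributed areas around the mean footprint.
    shape = 1.0 / area_cv**2
    areas = rng.gamma(shape, mean_area_px / shape, size=n_chrom)
    radii = np.sqrt(areas / np.pi)
    # Rejection-sample centers; discs must not overlap and must fit inside.
    order = np.argsort(-radii)  # place big discs first
    positions = np.full((n_chrom, 2), np.nan)
    placed_r: list[float] = []
    placed_xy: list[np.ndarray] = []
    max_attempts = 2000
    for idx in order:
        r = radii[idx]
        for _ in range(max_attempts):
            p = rng.uniform([r + 1, r + 1], [H - r - 1, W - r - 1])
            ok = True
            for q, rq in zip(placed_xy, placed_r):
                if np.hypot(*(p - q)) < r + rq + margin_px:
                    ok = False
                    break
            if ok:
                positions[idx] = p
                placed_xy.append(p)
                placed_r.append(r)
                break
        else:
            raise RuntimeError(
                f"could not place disc {idx} after {max_attempts} attempts: "
                "density infeasible"
            )
    if layout == "interdigitated":
        labels = rng.integers(0, k_components, size=n_chrom)
        # guarantee every label appears
        labels[:k_components] = np.arange(k_components)
        rng.shuffle(labels)
    elif layout == "patches":
        labels = _spatial_labels(positions, k_components, rng)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return SceneTruth(positions, radii, labels, (H, W))


def _spatial_labels(positions: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous spatial patches via a few Lloyd iterations on positions."""
    if k == 1:
        return np.zeros(positions.shape[0], dtype=int)
    centers = positions[rng.choice(positions.shape[0], size=k, replace=False)]
    labels = np.zeros(positions.shape[0], dtype=int)
    for _ in range(20):
        d = np.linalg.norm(positions[:, None, :] - centers[None, :, :], axis=2)
        labels = np.argmin(d, axis=1)
        for j in range(k):
            sel = labels == j
            if sel.any():
                centers[j] = positions[sel].mean(axis=0)
    # relabel to cover 0..K-1 even if a cluster emptied
    uniq, labels = np.unique(labels, return_inverse=True)
    return labels


# ----------------------------------------------------------- area time series


def gen_component_timeseries(
    scene: SceneTruth,
    T: int,
    loadings: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
) -> AreaMatrix:
    """Area series where chromatophore ``i`` follows its component's loading
    plus iid Gaussian noise, clipped at zero.

    ``loadings`` is ``(K, T)`` with K equal to the scene's component count.
    The ground-truth partition is ``scene.component_labels``.
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape != (scene.k_components, T):
        raise ValueError(
            f"loadings must be (K={scene.k_components}, T={T}), got {loadings.shape}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    values = loadings[scene.component_labels].T  # (T, N)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return AreaMatrix(np.clip(values, 0.0, None), rate=rate)


# ---------------------------------------------------------------- trajectories


def _rotate2(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _make_waypoints(truth: TrajectoryTruth, rng: np.random.Generator) -> np.ndarray:
    """Generate slow-point locations from the heading rule of ``truth.model``.

    The heading noise ``truth.noise_sd`` is an angular jitter (radians) applied
    to each exit direction; waypoint generation is 2-D.
    """
    start, goal = truth.start, truth.goal
    if start.size != 2:
        raise ValueError("automatic waypoint generation requires 2-D start/goal")
    n = truth.n_waypoints
    pts = [start.astype(float)]
    fixed_dir = goal - start
    fixed_dir = fixed_dir / np.linalg.norm(fixed_dir)
    step0 = np.linalg.norm(goal - start) / (n + 1)
    for k in range(n):
        p = pts[-1]
        if truth.model == "update":
            to_goal = goal - p
            dist = np.linalg.norm(to_goal)
            if dist < 1e-12:  # already converged (noise-free corner case)
                break
            heading = to_goal / dist
            # each step re-aims at the goal and covers step_gain of the
            # remaining distance; the angular noise makes it miss laterally,
            # so the residual error direction randomizes step to step
            step = truth.step_gain * dist
        else:  # memory: fixed initial heading, never corrected
            heading = fixed_dir
            step = step0
        heading = _rotate2(heading, rng.normal(0.0, truth.noise_sd))
        pts.append(p + step * heading)
    if truth.model == "update":
        # the update rule converges on the goal; the memory rule ends
        # wherever its fixed heading took it (its endpoint IS the measured
        # goal, the final stabilized pattern)
        pts.append(goal.astype(float))
    return np.asarray(pts[1:])  # waypoints exclude the start


def _raised_cosine_positions(n: int) -> np.ndarray:
    """Fractional progress along a segment with raised-cosine speed: the
    speed profile is sin^2, so endpoints are unambiguous local speed minima."""
    t = np.linspace(0.0, 1.0, n + 1)[1:]
    return t - np.sin(2 * np.pi * t) / (2 * np.pi)


def gen_transition_trajectory(
    truth: TrajectoryTruth, T: int, seed: int = 0, rate: float = DEFAULT_RATE,
    pos_noise_sd: float = 0.0,
) -> FeatureTrajectory:
    """Render a planted trajectory with raised-cosine motion between waypoints
    and explicit dwell at each one.

    For the ``update`` and ``memory`` models, waypoints are generated from the
    model's heading rule when ``truth.waypoints`` is None (and written back to
    ``truth`` as exported ground truth). ``ballistic`` is a single direct
    excursion from start to goal and back. Ground-truth slow-point frames are
    stored on ``truth.slow_point_frames`` and the outward-phase mask of the
    ballistic model on ``truth.outward_mask``.
    """
    rng = np.random.default_rng(seed)
    if truth.model == "ballistic":
        nodes = np.vstack([truth.start, truth.goal, truth.start])
    else:
        if truth.waypoints is None:
            truth.waypoints = _make_waypoints(truth, rng)
        nodes = np.vstack([truth.start, truth.waypoints])
    n_seg = nodes.shape[0] - 1
    n_nodes = nodes.shape[0]
    dwell = truth.dwell_frames
    if np.isscalar(dwell):
        dwell_arr = np.full(n_nodes, int(dwell))
    else:
        dwell_arr = np.asarray(dwell, dtype=int)
        if dwell_arr.size != n_nodes:
            raise ValueError("dwell_frames must be scalar or one per node")
    total_dwell = int(dwell_arr.sum())
    move_frames = T - total_dwell
    if move_frames < 2 * n_seg:
        raise ValueError(
            f"T={T} too short to honor dwell_frames ({total_dwell}) "
            f"plus {n_seg} motion segments"
        )
    per_seg = np.full(n_seg, move_frames // n_seg)
    per_seg[: move_frames % n_seg] += 1
    coords: list[np.ndarray] = []
    slow_frames: list[int] = []
    frame = 0
    for i in range(n_nodes):
        d = int(dwell_arr[i])
        if d > 0:
            coords.append(np.tile(nodes[i], (d, 1)))
            slow_frames.append(frame + d // 2)
            frame += d
        else:
            slow_frames.append(max(frame - 1, 0))
        if i < n_seg:
            frac = _raised_cosine_positions(per_seg[i])
            seg = nodes[i] + frac[:, None] * (nodes[i + 1] - nodes[i])
            coords.append(seg)
            frame += per_seg[i]
    path = np.vstack(coords)
    if pos_noise_sd > 0:
        path = path + rng.normal(0.0, pos_noise_sd, size=path.shape)
    truth.slow_point_frames = np.asarray(slow_frames[1:-1] if truth.model != "ballistic" else slow_frames, dtype=int)
    if truth.model == "ballistic":
        out_end = dwell_arr[0] + per_seg[0]
        mask = np.zeros(path.shape[0], dtype=bool)
        mask[dwell_arr[0]: out_end] = True
        truth.outward_mask = mask
    return FeatureTrajectory(path, rate=rate, label=f"synthetic-{truth.model}")


# ------------------------------------------------------------------ backgrounds


def gen_background(
    kind: str, params: dict | None = None, seed: int = 0
) -> np.ndarray:
    """Synthesize a background texture image (float array).

    kinds: ``checkerboard`` (params: size=(H,W), square_px; exact binary
    0/255), ``one_over_f`` (params: size, alpha; radially averaged power
    spectrum with log-log slope -alpha), ``blobs`` (thresholded smoothed
    noise).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    H, W = params.get("size", (256, 256))
    if kind == "checkerboard":
        sq = int(params.get("square_px", 8))
        if sq < 1:
            raise ValueError("square size must be >= 1 px")
        rows = (np.arange(H) // sq) % 2
        cols = (np.arange(W) // sq) % 2
        return 255.0 * ((rows[:, None] + cols[None, :]) % 2)
    if kind == "one_over_f":
        alpha = float(params.get("alpha", 2.0))
        if alpha < 0:
            raise ValueError("spectral exponent alpha must be >= 0")
        fy = np.fft.fftfreq(H)[:, None]
        fx = np.fft.fftfreq(W)[None, :]
        f = np.hypot(fy, fx)
        f[0, 0] = 1.0  # DC untouched (set to 0 below)
        amp = f ** (-alpha / 2.0)
        amp[0, 0] = 0.0
        phase = rng.uniform(0, 2 * np.pi, size=(H, W))
        spec = amp * np.exp(1j * phase)
        img = np.real(np.fft.ifft2(spec))
        img = img - img.mean()
        sd = img.std()
        return img / sd if sd > 0 else img
    if kind == "blobs":
        from scipy.ndimage import gaussian_filter

        sigma = float(params.get("sigma", 6.0))
        img = gaussian_filter(rng.normal(size=(H, W)), sigma)
        return 255.0 * (img > np.median(img))
    raise ValueError(f"unknown background kind {kind!r}")


# --------------------------------------------------------------------- looming


def gen_looming(
    l_over_v: float,
    d: float,
    onset_angle: float = 1.5,
    rate: float = 60.0,
) -> LoomingStimulus:
    """Looming-disc stimulus: ``r(t) = d * (l/v) / tau`` with ``tau`` the time
    remaining to collision.

    The series starts when the angular size equals ``onset_angle`` (degrees),
    i.e. at ``tau = (l/v) / tan(onset_angle / 2)``, and ends one frame before
    ``tau = 0``.
    """
    if l_over_v <= 0 or d <= 0:
        raise ValueError("l_over_v and d must be positive")
    if not (0 < onset_angle < 180):
        raise ValueError("onset_angle must be in (0, 180) degrees")
    tau_onset = l_over_v / np.tan(np.radians(onset_angle) / 2.0)
    n = int(np.floor(tau_onset * rate))  # frames strictly before collision
    tau = tau_onset - np.arange(n) / rate
    tau = tau[tau > 1e-12]
    r = d * l_over_v / tau
    theta = 2.0 * np.degrees(np.arctan(r / d))
    return LoomingStimulus(l_over_v, d, onset_angle, rate, r, theta, tau)


# -------------------------------------------------------------- blanch trials


def _raised_cosine_ramp(n: int) -> np.ndarray:
    """Monotone 0->1 ramp over n samples (half raised cosine)."""
    return 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n)))


def gen_blanch_trial(
    scene: SceneTruth,
    T: int,
    recruitment_order: list[int] | np.ndarray,
    blanch_depth: float = 0.3,
    seed: int = 0,
    rate: float = DEFAULT_RATE,
    noise_sd: float = 0.0,
    onset_jitter_s: float = 0.0,
    onset_gap_s: float = 1.5,
) -> tuple[AreaMatrix, dict]:
    """A threat-evoked blanching trial: all areas fall rapidly to
    ``blanch_depth`` x their starting value, then components re-expand in
    ``recruitment_order`` with staggered onsets.

    Returns the AreaMatrix and a ground-truth dict with the planted component
    onset frames (``component_onsets``), per-chromatophore onset frames
    (``chrom_onsets``) and the blanch-minimum frame (``blanch_frame``).
    """
    if not (0.0 < blanch_depth < 1.0):
        raise ValueError("blanch_depth must be in (0, 1)")
    order = np.asarray(recruitment_order, dtype=int)
    if sorted(order.tolist()) != list(range(scene.k_components)):
        raise ValueError("recruitment_order must be a permutation of component labels")
    rng = np.random.default_rng(seed)
    base = np.pi * scene.radii**2  # starting (fully camouflaged) areas
    N = scene.n_chrom
    pre = int(round(1.0 * rate))           # 1 s of stable camouflage
    drop = int(round(0.5 * rate))          # rapid collapse
    hold = int(round(0.5 * rate))          # blanched plateau
    rise = int(round(1.0 * rate))          # per-component re-expansion
    gap = int(round(onset_gap_s * rate))   # stagger between components
    first_onset = pre + drop + hold
    need = first_onset + gap * (scene.k_components - 1) + rise + 1
    if T < need:
        raise ValueError(f"T={T} too short for blanch profile (need >= {need})")
    frac = np.ones((T, N))
    ramp_down = 1.0 - (1.0 - blanch_depth) * _raised_cosine_ramp(drop)
    frac[pre: pre + drop] = ramp_down[:, None]
    frac[pre + drop:] = blanch_depth
    chrom_onsets = np.zeros(N, dtype=float)
    comp_onsets = {}
    for rank, comp in enumerate(order):
        onset = first_onset + rank * gap
        comp_onsets[int(comp)] = onset
        for i in np.flatnonzero(scene.component_labels == comp):
            o = onset
            if onset_jitter_s > 0:
                o = int(round(onset + rng.uniform(-1, 1) * onset_jitter_s * rate))
                o = max(pre + drop, min(o, T - rise - 1))
            chrom_onsets[i] = o
            up = blanch_depth + (1.0 - blanch_depth) * _raised_cosine_ramp(rise)
            frac[o: o + rise, i] = up
            frac[o + rise:, i] = 1.0
    values = frac * base[None, :]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd * base.mean(), size=values.shape)
    truth = {
        "component_onsets": comp_onsets,
        "chrom_onsets": chrom_onsets,
        "blanch_frame": pre + drop + hold // 2,
        "recruitment_order": order.tolist(),
    }
    return AreaMatrix(np.clip(values, 0.0, None), rate=rate), truth


# ------------------------------------------------------------------- rendering


def render_frames(
    scene: SceneTruth,
    areas: AreaMatrix,
    background_gray: int = 200,
    disc_gray: int = 20,
    max_expand: float = 1.5,
) -> np.ndarray:
    """Rasterize each chromatophore as a filled dark disc whose pixel count
    equals its area value (exact nearest-pixel rasterization, no blur).

    A chromatophore's footprint is capped at ``max_expand`` times its nominal
    scene radius; larger requested areas are clipped with a warning.
    """
    if areas.n_chrom != scene.n_chrom:
        raise ValueError("areas and scene disagree on chromatophore count")
    H, W = scene.image_size
    T = areas.n_frames
    # Precompute, per disc, pixel coordinates sorted by distance from center.
    sorted_pix: list[np.ndarray] = []
    caps: list[int] = []
    for p, r in zip(scene.positions, scene.radii):
        rmax = max_expand * r
        r0 = int(np.floor(p[0] - rmax)), int(np.ceil(p[0] + rmax)) + 1
        c0 = int(np.floor(p[1] - rmax)), int(np.ceil(p[1] + rmax)) + 1
        rr, cc = np.mgrid[max(r0[0], 0): min(r0[1], H), max(c0[0], 0): min(c0[1], W)]
        rr, cc = rr.ravel(), cc.ravel()
        d2 = (rr + 0.5 - p[0]) ** 2 + (cc + 0.5 - p[1]) ** 2
        inside = d2 <= rmax**2
        rr, cc, d2 = rr[inside], cc[inside], d2[inside]
        order = np.lexsort((cc, rr, d2))  # deterministic tie-break
        sorted_pix.append(np.stack([rr[order], cc[order]], axis=1))
        caps.append(int(inside.sum()))
    clipped = False
    stack = np.full((T, H, W), background_gray, dtype=np.uint8)
    for t in range(T):
        frame = stack[t]
        for i, pix in enumerate(sorted_pix):
            npx = int(round(areas.values[t, i]))
            if npx > caps[i]:
                npx = caps[i]
                clipped = True
            if npx > 0:
                sel = pix[:npx]
                frame[sel[:, 0], sel[:, 1]] = disc_gray
    if clipped:
        warnings.warn("some requested areas exceeded the scene's footprint; clipped")
    return stack
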