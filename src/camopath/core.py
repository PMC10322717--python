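"""Shared domain types for chromatophore and pattern-space analysis.

The central object is the :class:`AreaMatrix` — a frames x chromatophores
matrix of expansion states sampled at a fixed frame rate (25 frames/s by
default). Trajectories through pattern space are :class:`FeatureTrajectory`
objects, optionally carrying the PCA basis they live in. Frame index ``i``
maps to time ``i / rate`` seconds; frame 0 is t = 0. Image coordinates are
row-major with the origin at the top-left, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AreaMatrix",
    "PCABasis",
    "FeatureTrajectory",
    "SlowPointAnnotation",
    "ComponentPartition",
    "SceneTruth",
    "TrajectoryTruth",
    "LoomingStimulus",
    "DEFAULT_RATE",
]

#: Acquisition frame rate of the imaging system, frames per second.
DEFAULT_RATE = 25.0


@dataclass
class AreaMatrix:
    """Chromatophore expansion states over time.

    Parameters
    ----------
    values
        ``(T, N)`` array of non-negative areas (arbitrary units; typically
        summed segmentation score per chromatophore region).
    rate
        Sampling rate in frames per second.
    valid_mask
        ``(T,)`` boolean; ``False`` marks blanked / artifact frames whose
        values must not enter any statistic.
    chrom_ids
        ``(N,)`` stable integer identifiers, unique.
    """

    values: np.ndarray
    rate: float = DEFAULT_RATE
    valid_mask: np.ndarray | None = None
    chrom_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("AreaMatrix values must be 2-D (frames x chromatophores)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        T, N = self.values.shape
        if self.valid_mask is None:
            self.valid_mask = ~np.any(np.isnan(self.values), axis=1)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (T,):
            raise ValueError("valid_mask must have one entry per frame")
        if self.chrom_ids is None:
            self.chrom_ids = np.arange(N, dtype=int)
        self.chrom_ids = np.asarray(self.chrom_ids, dtype=int)
        if self.chrom_ids.shape != (N,):
            raise ValueError("chrom_ids must have one entry per chromatophore")
        if len(np.unique(self.chrom_ids)) != N:
            raise ValueError("chrom_ids must be unique")
        valid_vals = self.values[self.valid_mask]
        if valid_vals.size and np.nanmin(valid_vals) < 0:
            raise ValueError("areas must be non-negative on valid frames")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_chrom(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame i at i / rate)."""
        return np.arange(self.n_frames) / self.rate

    def valid_values(self) -> np.ndarray:
        """Rows restricted to valid frames."""
        return self.values[self.valid_mask]

    def copy(self) -> "AreaMatrix":
        return AreaMatrix(
            self.values.copy(), self.rate, self.valid_mask.copy(), self.chrom_ids.copy()
        )


@dataclass
class PCABasis:
    """PCA metadata attached to a trajectory: loadings, variance fractions, centering."""

    components: np.ndarray  # (D, original_dim) loadings
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if evr.size and (evr.min() < -1e-12 or evr.max() > 1 + 1e-12):
            raise ValueError("explained-variance fractions must lie in [0, 1]")
        if evr.size > 1 and np.any(np.diff(evr) > 1e-10):
            raise ValueError("explained-variance fractions must be non-increasing")
        self.explained_variance_ratio = evr


@dataclass
class FeatureTrajectory:
    """A path through feature / PC space: ``(T, D)`` coordinates at a fixed rate."""

    coords: np.ndarray
    rate: float = DEFAULT_RATE
    basis: PCABasis | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("coords must be (T, D) with D >= 1")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate


@dataclass
class SlowPointAnnotation:
    """Low-velocity points of a trajectory with dwell intervals and phase labels.

    ``indices`` are frame indices of local speed minima (strictly increasing);
    ``dwell_intervals`` are inclusive ``(start, end)`` frame pairs, each
    containing its slow point; ``phase_mask`` marks each frame slow (True)
    or fast (False).
    """

    indices: np.ndarray
    dwell_intervals: list[tuple[int, int]]
    phase_mask: np.ndarray
    quartile_threshold: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("slow-point indices must be strictly increasing")
        if len(self.dwell_intervals) != self.indices.size:
            raise ValueError("one dwell interval per slow point required")
        for idx, (a, b) in zip(self.indices, self.dwell_intervals):
            if not (a <= idx <= b):
                raise ValueError("dwell interval must contain its slow point")

    @property
    def n_points(self) -> int:
        return int(self.indices.size)

    def dwell_times(self, rate: float) -> np.ndarray:
        """Dwell durations in seconds."""
        return np.array([(b - a + 1) / rate for a, b in self.dwell_intervals])


@dataclass
class ComponentPartition:
    """Assignment of every chromatophore to exactly one pattern component."""

    labels: np.ndarray
    params: dict = field(default_factory=dict)
    source: str = ""
    chrom_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.chrom_ids is None:
            self.chrom_ids = np.arange(self.labels.size, dtype=int)
        self.chrom_ids = np.asarray(self.chrom_ids, dtype=int)
        if self.chrom_ids.shape != self.labels.shape:
            raise ValueError("chrom_ids must match labels")

    @property
    def k(self) -> int:
        return int(len(np.unique(self.labels)))

    @property
    def n(self) -> int:
        return int(self.labels.size)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


@dataclass
class SceneTruth:
    """Synthetic-scene ground truth: disc positions/radii and component labels."""

    positions: np.ndarray  # (N, 2) as (row, col) pixel coordinates
    radii: np.ndarray
    component_labels: np.ndarray
    image_size: tuple[int, int]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.component_labels = np.asarray(self.component_labels, dtype=int)
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        H, W = self.image_size
        r = self.radii
        pos = self.positions
        if np.any(pos[:, 0] - r < 0) or np.any(pos[:, 0] + r > H) or np.any(
            pos[:, 1] - r < 0
        ) or np.any(pos[:, 1] + r > W):
            raise ValueError("all discs must fit inside the image")
        labels = np.unique(self.component_labels)
        if not np.array_equal(labels, np.arange(labels.size)):
            raise ValueError("component labels must cover 0..K-1")

    @property
    def n_chrom(self) -> int:
        return int(self.positions.shape[0])

    @property
    def k_components(self) -> int:
        return int(len(np.unique(self.component_labels)))


@dataclass
class TrajectoryTruth:
    """Planted trajectory structure: motion model, waypoints, dwell and noise.

    ``model`` selects the heading rule at each slow-point exit:
    ``update`` re-aims at the goal from the current state, ``memory`` keeps the
    initial start-to-goal direction, and ``ballistic`` is a single direct
    excursion (blanching-like). If ``waypoints`` is None they are generated
    from the model rule at simulation time.
    """

    model: str
    goal: np.ndarray
    start: np.ndarray
    waypoints: np.ndarray | None = None
    dwell_frames: Sequence[int] | int = 10
    noise_sd: float = 0.0
    n_waypoints: int = 5
    #: fraction of the remaining distance covered per update-model step;
    #: 1.0 means each step aims to land on the goal, missing by the noise
    step_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("update", "memory", "ballistic"):
            raise ValueError(f"unknown trajectory model {self.model!r}")
        self.goal = np.asarray(self.goal, dtype=float)
        self.start = np.asarray(self.start, dtype=float)
        if self.waypoints is not None:
            self.waypoints = np.asarray(self.waypoints, dtype=float)
            if self.model != "ballistic" and self.waypoints.shape[0] < 2:
                raise ValueError("transition models need at least 2 waypoints")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class LoomingStimulus:
    """Expanding-disc stimulus: radius and angular size against time to collision.

    The governing relation is ``r(t)/d = tan(theta/2) = (l/v)/tau`` with
    ``tau`` the time remaining to collision, ``l`` the half-width of the
    approaching object and ``v`` its speed.
    """

    l_over_v: float
    d: float
    onset_angle: float
    rate: float
    r_t: np.ndarray
    theta_t: np.ndarray
    tau_t: np.ndarray

    def __post_init__(self) -> None:
        self.r_t = np.asarray(self.r_t, dtype=float)
        self.theta_t = np.asarray(self.theta_t, dtype=float)
        self.tau_t = np.asarray(self.tau_t, dtype=float)
        if self.r_t.size > 1 and np.any(np.diff(self.r_t) <= 0):
            raise ValueError("radius must strictly increase toward collision")
        expected = 2.0 * np.degrees(np.arctan(self.r_t / self.d))
        if not np.allclose(self.theta_t, expected, rtol=1e-9, atol=1e-9):
            raise ValueError("theta_t inconsistent with 2*arctan(r/d)")

    @property
    def n_frames(self) -> int:
        return int(self.r_t.size)
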