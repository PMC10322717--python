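"""Single-view chromatophore extraction from grayscale image stacks.

The chain mirrors the standard pipeline: band-pass (difference-of-Gaussians)
detection of chromatophore-scale features, a focus statistic over frames, a
body mask from the smoothed band energy, watershed segmentation of the
time-averaged darkness score into chromatophore regions, and per-region score
sums as the area readout. A thresholded darkness score stands in for a learned
per-pixel chromatophore classifier; areas are therefore fractional
(sub-pixel) when the score is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import find_contours, label as cc_label
from skimage.segmentation import watershed

from .core import AreaMatrix, DEFAULT_RATE

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMap",
    "BodyMask",
    "dog_filter",
    "focus_statistic",
    "body_mask",
    "darkness_score",
    "segment_chromatophores",
    "extract_areas",
    "remove_artifacts",
    "detect_artifact_frames",
]

#: Default DoG sigma pair in pixels (wide, narrow), tuned to chromatophore-
#: scale features at the 54 px mean footprint; rescalable by mean radius.
DOG_SIGMAS = (2.0, 1.0)

#: Smallest credible chromatophore region in pixels.
MIN_REGION_PX = 9


@dataclass
class LabelMap:
    """Watershed chromatophore regions: 0 = background, labels 1..R."""

    labels: np.ndarray
    region_areas: dict[int, int] = field(default_factory=dict)
    dropped: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.region_areas:
            ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
            self.region_areas = dict(zip(ids.tolist(), counts.tolist()))

    @property
    def n_regions(self) -> int:
        return len(self.region_areas)

    def centroids(self) -> np.ndarray:
        """(R, 2) region centroids in (row, col), ordered by label."""
        ids = sorted(self.region_areas)
        return np.array(ndimage.center_of_mass(np.ones_like(self.labels), self.labels, ids))


@dataclass
class BodyMask:
    """Animal mask (single connected component) with its boundary contour."""

    mask: np.ndarray
    contour: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        n = cc_label(self.mask).max()
        if n != 1:
            raise ValueError(f"body mask must be one connected component, found {n}")


def dog_filter(image: np.ndarray, sigmas: tuple[float, float] = DOG_SIGMAS) -> np.ndarray:
    """Difference of Gaussians, fixed convention ``G(s1)*I - G(s2)*I`` with
    ``s1 > s2``; linear in the input. Output is float."""
    s1, s2 = sigmas
    if not (s1 > s2 > 0):
        raise ValueError("sigmas must satisfy s1 > s2 > 0")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("dog_filter expects a 2-D image")
    return ndimage.gaussian_filter(img, s1) - ndimage.gaussian_filter(img, s2)


def focus_statistic(
    stack: np.ndarray,
    sigmas: tuple[float, float] = DOG_SIGMAS,
    threshold: float | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-frame focus statistic and in-focus chunks.

    The statistic is the sum of |DoG| over pixels (the raw DoG sums to ~0, so
    the absolute value carries the band energy). Chunks are maximal runs of
    frames strictly above ``threshold`` (inclusive (start, end) frame pairs);
    with ``threshold=None`` only the series is computed. The usable threshold
    is dataset-specific and deliberately has no universal default.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("focus_statistic expects a (T, H, W) stack")
    stat = np.array([np.abs(dog_filter(fr, sigmas)).sum() for fr in stack])
    chunks: list[tuple[int, int]] = []
    if threshold is not None:
        above = stat > threshold
        edges = np.flatnonzero(np.diff(np.r_[False, above, False]))
        chunks = [(int(edges[i]), int(edges[i + 1] - 1)) for i in range(0, len(edges), 2)]
    return stat, chunks


def body_mask(
    image: np.ndarray,
    smooth_sd: float = 25.0,
    threshold: float | None = None,
    sigmas: tuple[float, float] = DOG_SIGMAS,
) -> BodyMask:
    """Mask the animal: |DoG| band energy, Gaussian smoothing (s.d. 25 px by
    default), threshold, largest connected component.

    ``threshold=None`` uses half of the smoothed image's maximum. Raises a
    'no animal' error on empty foreground.
    """
    energy = np.abs(dog_filter(image, sigmas))
    smooth = ndimage.gaussian_filter(energy, smooth_sd, mode="nearest")
    if threshold is None:
        threshold = 0.3 * smooth.max()
    # band energy concentrates on boundaries; fill enclosed interiors
    fg = ndimage.binary_fill_holes(smooth > threshold)
    lab = cc_label(fg)
    if lab.max() == 0:
        raise ValueError("no animal: empty foreground after thresholding")
    sizes = np.bincount(lab.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    mask = lab == keep
    contours = find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len) if contours else np.empty((0, 2))
    return BodyMask(mask, contour)


def darkness_score(
    image: np.ndarray, background: float | None = None, dark: float | None = None
) -> np.ndarray:
    """Normalized darkness in [0, 1]: 1 at fully dark (chromatophore) pixels,
    0 at background. Defaults estimate background as the median intensity and
    dark as the minimum."""
    img = np.asarray(image, dtype=float)
    if background is None:
        background = float(np.median(img))
    if dark is None:
        dark = float(img.min())
    if background <= dark:
        return np.zeros_like(img)
    return np.clip((background - img) / (background - dark), 0.0, 1.0)


def segment_chromatophores(
    mean_frame: np.ndarray,
    mask: BodyMask | np.ndarray | None = None,
    min_region_px: int = MIN_REGION_PX,
    score_threshold: float = 0.5,
    seed_sigma: float = 1.0,
    min_seed_distance: int = 3,
) -> LabelMap:
    """Watershed the time-averaged chromatophore score into regions.

    ``mean_frame`` is the darkness-score average (high = chromatophore).
    Seeds are regional maxima of the score smoothed with ``seed_sigma``; the
    flooding surface is the inverted (smoothed) score, restricted to
    score > ``score_threshold`` within the body mask. Regions smaller than
    ``min_region_px`` are dropped and flagged. Ties on seed plateaus resolve
    by first-scan order, so the result is deterministic.
    """
    score = np.asarray(mean_frame, dtype=float)
    fg = score > score_threshold
    if mask is not None:
        m = mask.mask if isinstance(mask, BodyMask) else np.asarray(mask, dtype=bool)
        fg &= m
    if not fg.any():
        warnings.warn("zero chromatophore regions found")
        return LabelMap(np.zeros_like(score, dtype=int))
    smooth = ndimage.gaussian_filter(score, seed_sigma)
    peaks = peak_local_max(
        smooth, min_distance=min_seed_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros_like(score, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        warnings.warn("zero chromatophore regions found")
        return LabelMap(np.zeros_like(score, dtype=int))
    lab = watershed(-smooth, markers=markers, mask=fg)
    # drop undersized regions, relabel contiguously
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    dropped = [int(i) for i, c in zip(ids, counts) if c < min_region_px]
    if dropped:
        logger.info("dropping %d regions below %d px", len(dropped), min_region_px)
        lab[np.isin(lab, dropped)] = 0
    out = np.zeros_like(lab)
    for new, old in enumerate(np.unique(lab[lab > 0]), start=1):
        out[lab == old] = new
    return LabelMap(out, dropped=dropped)


def extract_areas(
    label_map: LabelMap, score_stack: np.ndarray, rate: float = DEFAULT_RATE
) -> AreaMatrix:
    """Per-frame chromatophore areas: sum of the score within every region.

    Fractional (sub-pixel) values are expected when the score is continuous.
    The column order follows ascending region label.
    """
    stack = np.asarray(score_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1:] != label_map.labels.shape:
        raise ValueError("score stack dimensions must match the label map")
    ids = sorted(label_map.region_areas)
    if not ids:
        return AreaMatrix(np.zeros((stack.shape[0], 0)), rate=rate)
    T = stack.shape[0]
    values = np.empty((T, len(ids)))
    lab = label_map.labels
    for t in range(T):
        sums = ndimage.sum_labels(stack[t], lab, ids)
        values[t] = sums
    return AreaMatrix(values, rate=rate, chrom_ids=np.asarray(ids))


def detect_artifact_frames(areas: AreaMatrix, k: float = 8.0, n_pcs: int = 10) -> np.ndarray:
    """Frames with periodic sharp peaks in PCA speed (compression artifacts).

    Speed is the frame-to-frame displacement norm in the top PCs of the
    (centered) area matrix; frames whose speed exceeds the median by more than
    ``k`` times the MAD are flagged.
    """
    vals = areas.values[areas.valid_mask]
    if vals.shape[0] < 3:
        return np.array([], dtype=int)
    centered = vals - vals.mean(axis=0)
    n_pcs = min(n_pcs, *centered.shape)
    # top-PC projection via SVD (deterministic)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[:n_pcs].T
    speed = np.linalg.norm(np.diff(proj, axis=0), axis=1)
    med = np.median(speed)
    mad = np.median(np.abs(speed - med))
    if mad == 0:
        return np.array([], dtype=int)
    spikes = np.flatnonzero(speed > med + k * mad)
    valid_idx = np.flatnonzero(areas.valid_mask)
    # a spike in the diff at position i implicates frame i+1
    return np.unique(valid_idx[np.minimum(spikes + 1, len(valid_idx) - 1)])


def remove_artifacts(
    areas: AreaMatrix,
    mode: str = "blank10",
    artifact_frames: np.ndarray | None = None,
    k: float = 8.0,
) -> AreaMatrix:
    """Clean compression artifacts from an area matrix.

    ``blank10`` invalidates a symmetric 10-frame window around each artifact
    (5 frames before through 4 after); ``median1s`` applies a centered 1 s
    median filter per chromatophore, which is the right choice when the
    per-frame sequence of activation matters.
    """
    out = areas.copy()
    if mode == "blank10":
        if artifact_frames is None:
            artifact_frames = detect_artifact_frames(areas, k=k)
        for f in np.asarray(artifact_frames, dtype=int):
            lo, hi = max(f - 5, 0), min(f + 5, areas.n_frames)
            out.valid_mask[lo:hi] = False
        return out
    if mode == "median1s":
        win = int(round(areas.rate))
        if win % 2 == 0:
            win += 1
        out.values = ndimage.median_filter(out.values, size=(win, 1), mode="nearest")
        return out
    raise ValueError(f"unknown artifact-removal mode {mode!r}")
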