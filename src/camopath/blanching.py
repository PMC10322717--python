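"""Analysis of threat-evoked blanching and recovery.

Blanching is a rapid whole-body chromatophore shrinkage followed by a slower,
structured return toward the prior camouflage. This module selects usable
trials, splits excursions into fast outward/return phases, extracts
per-chromatophore recruitment onsets and ranks during the return, quantifies
rank reliability across trials (bin densities with an analytic s.d.),
tests component-wise rank ordering (Kruskal-Wallis plus pairwise permutation
tests with Benjamini-Hochberg correction), clusters blanched vs end patterns
to probe pattern memory, and measures trajectory curvature after arclength
reparameterization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.interpolate import CubicSpline
from scipy.signal.windows import hann
from scipy.spatial.distance import directed_hausdorff, pdist, squareform
from statsmodels.stats.multitest import multipletests

from .components import leiden_components, reconstruction_variance, shuffled_partition
from .core import AreaMatrix, ComponentPartition, FeatureTrajectory
from .dynamics import SpeedProfile

logger = logging.getLogger(__name__)

__all__ = [
    "RecruitmentRanks",
    "RankDensity",
    "CurvatureProfile",
    "select_blanch_trials",
    "fast_phase",
    "recruitment_times",
    "aggregate_ranks",
    "rank_density",
    "component_rank_test",
    "mantel_test",
    "pattern_memory_clustering",
    "event_patterns",
    "trajectory_curvature",
    "select_similar_trials",
    "bytrial_vs_alltrial_variance",
]

#: Trial-selection thresholds: early-drop criterion and low-vigour floor
#: (fractions of the mean starting size).
DROP_FRACTION = 0.90
VIGOUR_FRACTION = 0.50
#: Recruitment extraction defaults.
MIN_INCREASE = 0.15
RECRUIT_THRESHOLD = 0.10


@dataclass
class RecruitmentRanks:
    """Per-chromatophore recruitment ranks over trials (normalized to [0, 1]).

    ``ranks`` is (n_trials, N) with NaN for chromatophores not selected in a
    trial; ``mu`` and ``sigma`` are the observed mean and s.d. of each
    chromatophore's normalized rank over the trials where it was selected.
    """

    ranks: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray


@dataclass
class RankDensity:
    """Histogram of mean recruitment ranks with its analytic s.d.

    ``sigma_bins[b] = sqrt(sum_i p_i (1 - p_i))`` where ``p_i`` is the
    probability that chromatophore i, with rank ~ Normal(mu_i, sigma_i),
    falls in bin b. A chromatophore with sigma_i = 0 is a point mass.
    """

    bin_edges: np.ndarray
    bin_density: np.ndarray
    sigma_bins: np.ndarray
    p_matrix: np.ndarray  # (N, n_bins)


@dataclass
class CurvatureProfile:
    """Unit tangents along arclength and the turn per unit-arclength step."""

    tangents: np.ndarray
    curvature: np.ndarray

    @property
    def mean_curvature(self) -> float:
        return float(self.curvature.mean()) if self.curvature.size else 0.0


# ------------------------------------------------------------ trial selection


def select_blanch_trials(trials: list[AreaMatrix]) -> dict:
    """Apply the two-tier blanching trial filter.

    A trial is kept when its mean chromatophore size drops below 90% of the
    mean starting size within the first 2 s. Kept trials whose blanching
    minimum stays above 50% of the start are low-vigour: usable for
    return-speed statistics but excluded from component analyses.
    """
    kept, kept_components, rejected = [], [], []
    for i, am in enumerate(trials):
        if am.n_frames / am.rate < 4.0:
            rejected.append((i, "trial shorter than 4 s"))
            continue
        trace = am.values[am.valid_mask].mean(axis=1)
        n0 = max(1, int(round(0.2 * am.rate)))
        start = trace[:n0].mean()
        first2s = trace[: int(round(2.0 * am.rate))]
        if first2s.min() >= DROP_FRACTION * start:
            rejected.append((i, "no drop below 90% of start in first 2 s"))
            continue
        kept.append(i)
        if trace.min() <= VIGOUR_FRACTION * start:
            kept_components.append(i)
        else:
            rejected.append((i, "low vigour: minimum above 50% of start "
                                "(kept for return-speed statistics only)"))
    return {"kept": kept, "kept_components": kept_components, "rejected": rejected}


# ------------------------------------------------------------------ fast phase


def _hann_smooth(x: np.ndarray, win: int) -> np.ndarray:
    if win < 3:
        return x.copy()
    w = hann(win)
    w = w / w.sum()
    return np.convolve(x, w, mode="same")


def fast_phase(
    speed: SpeedProfile,
    split_frame: int,
    window_s: float = 4.0,
    frac: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast-phase masks of the outward and return excursions.

    The speed profile is smoothed with a Hann window (4 s default); within
    each segment (before/after ``split_frame``, the frame of maximum
    blanching) the mask marks samples above ``frac`` of that segment's peak.
    """
    v = np.nan_to_num(np.asarray(speed.values, dtype=float), nan=0.0)
    sm = _hann_smooth(v, int(round(window_s * speed.rate)))
    masks = []
    for seg in (slice(0, split_frame), slice(split_frame, v.size)):
        peak = sm[seg].max() if sm[seg].size else 0.0
        if peak <= 0:
            raise ValueError("zero peak speed in excursion segment")
        m = np.zeros(v.size, dtype=bool)
        m[seg] = sm[seg] > frac * peak
        masks.append(m)
    return masks[0], masks[1]


# ------------------------------------------------------------- recruitment


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(axis=0), x.max(axis=0)
    rng = np.where(hi > lo, hi - lo, 1.0)
    return (x - lo) / rng


def recruitment_times(
    areas: AreaMatrix,
    min_increase: float = MIN_INCREASE,
    smooth_s: float = 1.0,
    threshold: float = RECRUIT_THRESHOLD,
    return_start: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Recruitment onsets and ranks during the return from blanching.

    Traces are median-filtered (1 s) and min-max normalized per
    chromatophore; the return segment starts at the global minimum of the
    mean area (maximum blanching) unless given. Chromatophores with a
    normalized increase of at least ``min_increase`` during the return are
    selected; their onset is the first upward crossing of ``threshold`` after
    Hann smoothing (1 s) and renewed min-max normalization. Ranks (average
    method for ties) are returned alongside; both arrays hold NaN for
    unselected chromatophores.
    """
    from scipy.ndimage import median_filter

    vals = areas.values[areas.valid_mask]
    win = int(round(areas.rate))
    win += (win + 1) % 2
    filt = median_filter(vals, size=(win, 1), mode="nearest")
    norm = _minmax(filt)
    if return_start is None:
        return_start = int(np.argmin(norm.mean(axis=1)))
    ret = norm[return_start:]
    increase = ret.max(axis=0) - ret[0]
    selected = increase >= min_increase
    if not selected.any():
        logger.warning("recruitment_times: no qualifying chromatophores")
        return np.full(areas.n_chrom, np.nan), np.full(areas.n_chrom, np.nan)
    sm = np.column_stack(
        [_hann_smooth(ret[:, i], int(round(smooth_s * areas.rate))) for i in range(ret.shape[1])]
    )
    sm = _minmax(sm)
    onsets = np.full(areas.n_chrom, np.nan)
    for i in np.flatnonzero(selected):
        above = np.flatnonzero(sm[1:, i] >= threshold)
        cross = [j for j in above if sm[j, i] < threshold]
        first = cross[0] + 1 if cross else (above[0] + 1 if above.size else None)
        if first is not None:
            onsets[i] = return_start + first
    sel = ~np.isnan(onsets)
    ranks = np.full(areas.n_chrom, np.nan)
    ranks[sel] = stats.rankdata(onsets[sel], method="average")
    return onsets, ranks


def aggregate_ranks(ranks_per_trial: np.ndarray) -> RecruitmentRanks:
    """Normalize per-trial ranks to [0, 1] and summarize per chromatophore."""
    R = np.asarray(ranks_per_trial, dtype=float)
    norm = np.full_like(R, np.nan)
    for t in range(R.shape[0]):
        sel = ~np.isnan(R[t])
        n = sel.sum()
        if n > 1:
            norm[t, sel] = (R[t, sel] - 1) / (n - 1)
        elif n == 1:
            norm[t, sel] = 0.5
    mu = np.nanmean(norm, axis=0)
    with np.errstate(invalid="ignore"):
        sigma = np.nanstd(norm, axis=0)
    return RecruitmentRanks(norm, mu, sigma)


def rank_density(ranks: RecruitmentRanks, n_bins: int = 50) -> RankDensity:
    """Bin the mean normalized ranks and compute the analytic bin s.d."""
    mu, sigma = ranks.mu, ranks.sigma
    ok = ~np.isnan(mu)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(mu[ok], 0, 1 - 1e-12), bins=edges)
    p = np.zeros((mu.size, n_bins))
    for i in np.flatnonzero(ok):
        if sigma[i] > 0:
            cdf = stats.norm.cdf(edges, loc=mu[i], scale=sigma[i])
            p[i] = np.diff(cdf)
        else:  # point mass
            b = min(int(mu[i] * n_bins), n_bins - 1)
            p[i, b] = 1.0
    sigma_bins = np.sqrt(np.sum(p * (1 - p), axis=0))
    return RankDensity(edges, counts.astype(float), sigma_bins, p)


def component_rank_test(
    mean_ranks: np.ndarray,
    partition: ComponentPartition,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Kruskal-Wallis test of component-wise mean recruitment ranks, with
    post hoc pairwise label-permutation tests (BH-corrected).

    The permutation scheme shuffles chromatophore labels flat (not
    hierarchically by trial), which can be anticonservative when ranks are
    correlated within trials; the output flags this.
    """
    mu = np.asarray(mean_ranks, dtype=float)
    labels = partition.labels
    groups = []
    for lab in np.unique(labels):
        g = mu[(labels == lab) & ~np.isnan(mu)]
        if g.size >= 2:
            groups.append((int(lab), g))
    if len(groups) < 2:
        raise ValueError("need >= 2 components with >= 2 ranked chromatophores")
    H, p = stats.kruskal(*[g for _, g in groups])
    rng = np.random.default_rng(seed)
    pair_p, pairs = [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            la, ga = groups[i]
            lb, gb = groups[j]
            obs = abs(ga.mean() - gb.mean())
            pool = np.concatenate([ga, gb])
            na = ga.size
            count = 0
            for _ in range(n_perm):
                rng.shuffle(pool)
                if abs(pool[:na].mean() - pool[na:].mean()) >= obs:
                    count += 1
            pairs.append((la, lb))
            pair_p.append((count + 1) / (n_perm + 1))
    rej, p_adj, *_ = multipletests(pair_p, method="fdr_bh")
    return {
        "H": float(H),
        "p": float(p),
        "pairs": pairs,
        "pairwise_p": np.asarray(pair_p),
        "pairwise_p_bh": p_adj,
        "component_means": {lab: float(g.mean()) for lab, g in groups},
        "permutation_scheme": "flat chromatophore-level (anticonservative "
                              "under within-trial correlation)",
    }


# -------------------------------------------------------------- pattern memory


def mantel_test(
    d1: np.ndarray, d2: np.ndarray, n_perm: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of two distance matrices with a
    permutation null over item labels. Returns (r, p)."""
    D1 = squareform(d1) if d1.ndim == 1 else np.asarray(d1, float)
    D2 = squareform(d2) if d2.ndim == 1 else np.asarray(d2, float)
    n = D1.shape[0]
    iu = np.triu_indices(n, 1)
    r_obs = np.corrcoef(D1[iu], D2[iu])[0, 1]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if np.corrcoef(D1[iu], D2[perm][:, perm][iu])[0, 1] >= r_obs:
            count += 1
    return float(r_obs), (count + 1) / (n_perm + 1)


def event_patterns(areas: AreaMatrix, frame: int, window: int = 10) -> np.ndarray:
    """Pattern at an event: the 10-frame (0.4 s) average around ``frame``."""
    lo = max(0, frame - window // 2)
    return areas.values[lo: lo + window].mean(axis=0)


def pattern_memory_clustering(
    blanch_patterns: np.ndarray,
    end_patterns: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
) -> dict:
    """Hierarchical clustering (correlation distance, complete linkage) of
    blanched and of end patterns, with the cophenetic correlation between the
    two trees and a Mantel test on the underlying distances.

    A high cophenetic correlation means the blanched states predict the
    patterns the animal returns to — a memory trace surviving blanching.
    """
    B = np.asarray(blanch_patterns, dtype=float)
    E = np.asarray(end_patterns, dtype=float)
    if B.shape[0] < 4:
        raise ValueError("need >= 4 trials")
    if np.any(B.std(axis=1) == 0) or np.any(E.std(axis=1) == 0):
        raise ValueError("constant pattern: correlation distance undefined")
    db = pdist(B, metric="correlation")
    de = pdist(E, metric="correlation")
    Zb = linkage(db, method="complete")
    Ze = linkage(de, method="complete")
    coph_b = cophenet(Zb)
    coph_e = cophenet(Ze)
    coph_r = float(np.corrcoef(coph_b, coph_e)[0, 1])
    r, p = mantel_test(db, de, n_perm=n_perm, seed=seed)
    return {
        "linkage_blanch": Zb,
        "linkage_end": Ze,
        "cophenetic_r": coph_r,
        "mantel_r": r,
        "mantel_p": p,
    }


# ------------------------------------------------------------------ curvature


def trajectory_curvature(
    traj: FeatureTrajectory,
    n_pcs: int | None = None,
    fast_mask: np.ndarray | None = None,
    step: float = 1.0,
) -> CurvatureProfile:
    """Curvature along the arclength-reparameterized trajectory.

    Coordinates are PCA-rotated per trial (top ``n_pcs``), fit with cubic
    splines against cumulative arclength, resampled at unit-arclength steps
    (``step`` feature units) so the path is traversed at unit speed, and the
    curvature per step is ``||T_{n+1} - T_n||`` of successive unit tangents.
    Dwell samples (zero displacement) are collapsed before fitting.
    """
    X = traj.coords
    if fast_mask is not None:
        X = X[np.asarray(fast_mask, dtype=bool)]
    if X.shape[0] < 4:
        raise ValueError("need >= 4 points after masking")
    Xc = X - X.mean(axis=0)
    if n_pcs is not None and n_pcs < X.shape[1]:
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        Xc = Xc @ vt[:n_pcs].T
    seg = np.linalg.norm(np.diff(Xc, axis=0), axis=1)
    keep = np.r_[True, seg > 1e-12]
    Xc = Xc[keep]
    if Xc.shape[0] < 4:
        raise ValueError("degenerate trajectory: too few distinct points")
    s = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(Xc, axis=0), axis=1))]
    total = s[-1]
    if total <= 2 * step:
        raise ValueError("degenerate (near zero-length) trajectory")
    spline = CubicSpline(s, Xc, axis=0)
    grid = np.arange(0.0, total + 1e-9, step)
    pts = spline(grid)
    d = np.diff(pts, axis=0)
    T = d / np.linalg.norm(d, axis=1, keepdims=True)
    curvature = np.linalg.norm(np.diff(T, axis=0), axis=1)
    return CurvatureProfile(T, curvature)


# ------------------------------------------------ by-trial vs all-trial power


def select_similar_trials(
    trajectories: list[FeatureTrajectory], cut_distance: float = 100.0
) -> list[int]:
    """Largest cluster of trajectories under Ward linkage on pairwise
    (symmetric) Hausdorff distances in the first two PCs.

    The cut distance is in dataset-dependent feature units and must be
    chosen per dataset.
    """
    n = len(trajectories)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = trajectories[i].coords[:, :2]
            b = trajectories[j].coords[:, :2]
            D[i, j] = D[j, i] = max(
                directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0]
            )
    Z = linkage(squareform(D), method="ward")
    labels = fcluster(Z, t=cut_distance, criterion="distance")
    sizes = np.bincount(labels)
    best = int(np.argmax(sizes[1:])) + 1
    return [i for i in range(n) if labels[i] == best]


def bytrial_vs_alltrial_variance(
    trials: list[AreaMatrix],
    resolution: float = 0.5,
    n_pcs: int = 200,
    n_pcs_cluster: int = 50,
    seed: int = 0,
) -> dict:
    """Generalizability of components: per-trial vs pooled decompositions.

    Leiden partitions are fit on each trial alone and on all trials pooled
    (concatenated in time); each trial's activity is reconstructed from
    component means under both, plus a shuffled by-trial control. The ratio
    by-trial / all-trial exceeds 1 when component structure is
    trial-specific.
    """
    if len(trials) < 3:
        raise ValueError("need >= 3 trials")
    pooled_vals = np.vstack([am.valid_values() for am in trials])
    pooled = AreaMatrix(pooled_vals, rate=trials[0].rate)
    part_all = leiden_components(
        pooled, n_pcs=n_pcs_cluster, resolution=resolution, seed=seed
    )
    by_trial, all_trial, shuffled, ratio = [], [], [], []
    for t, am in enumerate(trials):
        p_t = leiden_components(am, n_pcs=n_pcs_cluster, resolution=resolution, seed=seed)
        ev_by = reconstruction_variance(p_t, am, n_pcs=n_pcs)
        p_all_t = ComponentPartition(part_all.labels, params=part_all.params,
                                     chrom_ids=am.chrom_ids.copy())
        ev_all = reconstruction_variance(p_all_t, am, n_pcs=n_pcs)
        ev_sh = reconstruction_variance(
            shuffled_partition(p_t, seed=seed + t), am, n_pcs=n_pcs
        )
        by_trial.append(ev_by)
        all_trial.append(ev_all)
        shuffled.append(ev_sh)
        ratio.append(ev_by / ev_all if ev_all > 0 else np.inf)
    return {
        "by_trial": np.asarray(by_trial),
        "all_trial": np.asarray(all_trial),
        "shuffled": np.asarray(shuffled),
        "ratio": np.asarray(ratio),
        "k_by_trial": None,
    }
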