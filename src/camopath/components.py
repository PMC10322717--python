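"""Pattern-component decomposition and component-stability analysis.

Chromatophores are grouped into components by community detection on a
k-nearest-neighbour graph of their PCA loadings: the area matrix (frames x
chromatophores) is z-scored per chromatophore, decomposed by SVD, and each
chromatophore embedded by its loadings on the top 50 PCs. Leiden communities
(RBConfiguration objective, resolution 2 for camouflage transitions and 0.5
for blanching) are the pattern components.

Stability across trials is quantified by matching components between two
partitions (greedy by shared chromatophore count, mirroring the
largest-shared-proportion pairing; optimal assignment available), scored by
the mean intersection-over-union plus Wallace coefficients and the adjusted
Rand index, and related to the distance between the underlying transitions.
"""

from __future__ import annotations

import logging

import igraph as ig
import leidenalg
import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .core import AreaMatrix, ComponentPartition, FeatureTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "PartitionMatch",
    "leiden_components",
    "active_components",
    "reconstruction_variance",
    "shuffled_partition",
    "match_partitions",
    "wallace_coefficients",
    "transition_distance",
    "stability_vs_distance",
    "spatial_separation",
    "checkerboard_regression",
]

#: Defaults of the clustering stage.
N_PCS = 50
N_NEIGHBORS = 10
RESOLUTION_CAMOUFLAGE = 2.0
RESOLUTION_BLANCHING = 0.5


class PartitionMatch:
    """Matched component pairs between two partitions with similarity scores."""

    def __init__(self, pairs, iou_per_pair, mean_iou, wallace, ari):
        self.pairs = pairs
        self.iou_per_pair = np.asarray(iou_per_pair, dtype=float)
        self.mean_iou = float(mean_iou)
        self.wallace = wallace  # (W 1->2, W 2->1)
        self.ari = float(ari)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PartitionMatch(mean_iou={self.mean_iou:.3f}, ari={self.ari:.3f}, "
            f"pairs={len(self.pairs)})"
        )


def _zscore_columns(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def chromatophore_embedding(areas: AreaMatrix, n_pcs: int = N_PCS) -> np.ndarray:
    """(N, n_pcs) embedding: each chromatophore's loadings on the top PCs of
    the z-scored area matrix (columns of X projected on the left singular
    basis, i.e. rows of V*S)."""
    X = _zscore_columns(areas.valid_values())
    if X.shape[0] < n_pcs:
        logger.info(
            "leiden_components: T=%d < n_pcs=%d, reducing", X.shape[0], n_pcs
        )
        n_pcs = X.shape[0]
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_pcs, s.size)
    return (vt[:k].T * s[:k])  # (N, k)


def leiden_components(
    areas: AreaMatrix,
    n_pcs: int = N_PCS,
    n_neighbors: int = N_NEIGHBORS,
    resolution: float = RESOLUTION_CAMOUFLAGE,
    seed: int = 0,
) -> ComponentPartition:
    """Leiden community detection on the symmetric k-NN graph of
    chromatophore loadings. Deterministic for a fixed seed."""
    N = areas.n_chrom
    if N < n_neighbors + 1:
        raise ValueError(f"need more than n_neighbors={n_neighbors} chromatophores")
    emb = chromatophore_embedding(areas, n_pcs)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = set()
    for i in range(N):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))  # symmetrized, unweighted
    g = ig.Graph(n=N, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership, dtype=int)
    logger.info(
        "leiden_components: k=%d at resolution=%g (n_pcs=%d, n_neighbors=%d)",
        labels.max() + 1, resolution, n_pcs, n_neighbors,
    )
    return ComponentPartition(
        labels,
        params={
            "n_pcs": n_pcs,
            "n_neighbors": n_neighbors,
            "resolution": resolution,
            "seed": seed,
        },
        chrom_ids=areas.chrom_ids.copy(),
    )


def active_components(
    partition: ComponentPartition,
    areas: AreaMatrix,
    phase_mask: np.ndarray | None = None,
    threshold_sd: float = 1.0,
) -> np.ndarray:
    """Labels of components whose mean (z-scored) trace changed by more than
    ``threshold_sd`` during the window.

    The trace is the mean over the component's chromatophores of their
    z-scored areas, so the change is expressed in units of each
    chromatophore's own s.d.; a constant component is inactive by definition.
    """
    if partition.n != areas.n_chrom:
        raise ValueError("partition does not match areas")
    vals = areas.valid_values()
    if phase_mask is not None:
        pm = np.asarray(phase_mask, dtype=bool)[areas.valid_mask]
        if not pm.any():
            raise ValueError("empty phase window")
        vals_w = vals[pm]
    else:
        vals_w = vals
    mu, sd = vals.mean(axis=0), vals.std(axis=0)
    z = np.where(sd > 0, (vals_w - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    active = []
    edge = max(1, int(round(0.2 * areas.rate)))  # 0.2 s endpoint averages
    for lab in np.unique(partition.labels):
        trace = z[:, partition.labels == lab].mean(axis=1)
        change = abs(trace[-edge:].mean() - trace[:edge].mean())
        if change > threshold_sd:
            active.append(int(lab))
    return np.asarray(active, dtype=int)


def shuffled_partition(partition: ComponentPartition, seed: int = 0) -> ComponentPartition:
    """Randomize chromatophore-to-component assignment, keeping sizes."""
    rng = np.random.default_rng(seed)
    labels = partition.labels.copy()
    rng.shuffle(labels)
    return ComponentPartition(
        labels, params={**partition.params, "shuffled": True},
        source=partition.source, chrom_ids=partition.chrom_ids.copy(),
    )


def reconstruction_variance(
    partition: ComponentPartition,
    areas: AreaMatrix,
    n_pcs: int = 200,
    mode: str = "same",
    seed: int = 0,
) -> float:
    """Fraction of the trajectory's variance (in its top ``n_pcs`` PC space)
    explained after replacing every chromatophore's trace by its component's
    mean trace.

    ``mode='same'`` uses the partition as given (typically derived from the
    same trajectory); ``mode='shuffled'`` first randomizes the assignment.
    Partitions derived from other sources (nearest transition, pooled
    transitions, static patterns) are passed in directly and scored the same
    way. A singleton partition reconstructs exactly (fraction 1).
    """
    if partition.n != areas.n_chrom:
        raise ValueError("partition does not match areas")
    if mode == "shuffled":
        partition = shuffled_partition(partition, seed=seed)
    elif mode != "same":
        raise ValueError(f"unknown mode {mode!r}; pass the partition explicitly")
    X = areas.valid_values()
    Xc = X - X.mean(axis=0)
    simp = np.empty_like(Xc)
    for lab in np.unique(partition.labels):
        sel = partition.labels == lab
        simp[:, sel] = Xc[:, sel].mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_pcs, s.size)
    V = vt[:k].T
    orig_scores = Xc @ V
    simp_scores = simp @ V
    total = float(np.sum(orig_scores**2))
    if total == 0:
        return 1.0
    resid = float(np.sum((orig_scores - simp_scores) ** 2))
    return 1.0 - resid / total


def wallace_coefficients(labels1: np.ndarray, labels2: np.ndarray) -> tuple[float, float]:
    """Directional Wallace coefficients: fraction of co-clustered pairs in one
    partition that are also co-clustered in the other."""
    l1, l2 = np.asarray(labels1), np.asarray(labels2)
    ct = np.zeros((l1.max() + 1, l2.max() + 1))
    for a, b in zip(l1, l2):
        ct[a, b] += 1
    nij = np.sum(ct * (ct - 1)) / 2.0
    n1 = np.sum([c * (c - 1) / 2.0 for c in np.bincount(l1)])
    n2 = np.sum([c * (c - 1) / 2.0 for c in np.bincount(l2)])
    w12 = nij / n1 if n1 > 0 else np.nan
    w21 = nij / n2 if n2 > 0 else np.nan
    return float(w12), float(w21)


def match_partitions(
    p1: ComponentPartition, p2: ComponentPartition, method: str = "greedy"
) -> PartitionMatch:
    """Match components between two partitions of the same chromatophores.

    ``greedy`` pairs components by descending shared chromatophore count
    (ties broken toward the smaller label pair); ``optimal`` maximizes the
    summed IoU over pairings by linear assignment. Per-pair IoU is
    ``|A & B| / |A | B|``; ``mean_iou`` averages matched pairs. Wallace
    coefficients and the adjusted Rand index are computed over the full
    partitions.
    """
    if p1.n != p2.n or not np.array_equal(np.sort(p1.chrom_ids), np.sort(p2.chrom_ids)):
        raise ValueError("partitions must cover the same chromatophores")
    # align by chrom_id
    o1 = np.argsort(p1.chrom_ids)
    o2 = np.argsort(p2.chrom_ids)
    l1 = p1.labels[o1]
    l2 = p2.labels[o2]
    u1, l1 = np.unique(l1, return_inverse=True)
    u2, l2 = np.unique(l2, return_inverse=True)
    k1, k2 = len(u1), len(u2)
    shared = np.zeros((k1, k2), dtype=int)
    for a, b in zip(l1, l2):
        shared[a, b] += 1
    sizes1 = np.bincount(l1, minlength=k1)
    sizes2 = np.bincount(l2, minlength=k2)
    union = sizes1[:, None] + sizes2[None, :] - shared
    iou = np.where(union > 0, shared / np.maximum(union, 1), 0.0)
    pairs: list[tuple[int, int]] = []
    if method == "greedy":
        S = shared.astype(float).copy()
        for _ in range(min(k1, k2)):
            best = np.unravel_index(np.argmax(S), S.shape)  # first-scan tie-break
            if S[best] <= 0:
                break
            pairs.append((int(best[0]), int(best[1])))
            S[best[0], :] = -1
            S[:, best[1]] = -1
    elif method == "optimal":
        rows, cols = linear_sum_assignment(-iou)
        pairs = [(int(r), int(c)) for r, c in zip(rows, cols)]
    else:
        raise ValueError(f"unknown matching method {method!r}")
    iou_pairs = np.array([iou[r, c] for r, c in pairs])
    mean_iou = float(iou_pairs.mean()) if iou_pairs.size else 0.0
    return PartitionMatch(
        pairs=[(int(u1[r]), int(u2[c])) for r, c in pairs],
        iou_per_pair=iou_pairs,
        mean_iou=mean_iou,
        wallace=wallace_coefficients(l1, l2),
        ari=adjusted_rand_score(l1, l2),
    )


def transition_distance(
    traj1: FeatureTrajectory | np.ndarray,
    traj2: FeatureTrajectory | np.ndarray,
    dataset_sd: float = 1.0,
) -> float:
    """Mean of all pairwise point distances between two trajectories,
    normalized by the dataset s.d."""
    a = traj1.coords if isinstance(traj1, FeatureTrajectory) else np.asarray(traj1, float)
    b = traj2.coords if isinstance(traj2, FeatureTrajectory) else np.asarray(traj2, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty trajectory")
    if dataset_sd <= 0:
        raise ValueError("dataset_sd must be positive")
    return float(cdist(a, b).mean() / dataset_sd)


def stability_vs_distance(
    partitions: list[ComponentPartition],
    trajectories: list[FeatureTrajectory],
    dataset_sd: float = 1.0,
    seed: int = 0,
) -> dict:
    """Component stability against transition distance over all trajectory
    pairs, with a label-shuffled baseline."""
    if len(partitions) != len(trajectories) or len(partitions) < 2:
        raise ValueError("need >= 2 (partition, trajectory) pairs")
    rng = np.random.default_rng(seed)
    dist, iou, iou_shuf = [], [], []
    for i in range(len(partitions)):
        for j in range(i + 1, len(partitions)):
            dist.append(transition_distance(trajectories[i], trajectories[j], dataset_sd))
            iou.append(match_partitions(partitions[i], partitions[j]).mean_iou)
            pj = shuffled_partition(partitions[j], seed=int(rng.integers(2**31)))
            iou_shuf.append(match_partitions(partitions[i], pj).mean_iou)
    return {
        "distance": np.asarray(dist),
        "mean_iou": np.asarray(iou),
        "shuffled_iou": np.asarray(iou_shuf),
    }


def _wasserstein_2d(a: np.ndarray, b: np.ndarray, max_points: int, seed: int) -> float:
    """Earth-mover distance between uniform 2-D point clouds. Exact (linear
    assignment) for equal sizes; the larger cloud is subsampled to the
    smaller (capped at max_points), flagged via log."""
    rng = np.random.default_rng(seed)
    m = min(len(a), len(b), max_points)
    if len(a) > m:
        a = a[rng.choice(len(a), m, replace=False)]
        logger.info("wasserstein: subsampled first cloud to %d points", m)
    if len(b) > m:
        b = b[rng.choice(len(b), m, replace=False)]
        logger.info("wasserstein: subsampled second cloud to %d points", m)
    cost = cdist(a, b)
    r, c = linear_sum_assignment(cost)
    return float(cost[r, c].mean())


def spatial_separation(
    partition: ComponentPartition,
    positions: np.ndarray,
    bin_px: float = 16.0,
    max_points: int = 1000,
    seed: int = 0,
) -> dict:
    """Pairwise spatial relations between components: binned-overlap cosine
    similarity of 2-D occupancy histograms, mean pairwise distance, and
    Wasserstein (earth-mover) distance with Euclidean ground metric in
    pixels."""
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] != partition.n:
        raise ValueError("positions must cover all chromatophores")
    labels = np.unique(partition.labels)
    lo = pos.min(axis=0)
    hi = pos.max(axis=0) + 1e-9
    nb = np.maximum(((hi - lo) / bin_px).astype(int) + 1, 1)
    hists = {}
    for lab in labels:
        pts = pos[partition.labels == lab]
        h, _, _ = np.histogram2d(
            pts[:, 0], pts[:, 1], bins=nb, range=[[lo[0], lo[0] + nb[0] * bin_px],
                                                  [lo[1], lo[1] + nb[1] * bin_px]]
        )
        hists[lab] = h.ravel()
    out = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            ha, hb = hists[la], hists[lb]
            denom = np.linalg.norm(ha) * np.linalg.norm(hb)
            overlap = float(ha @ hb / denom) if denom > 0 else 0.0
            pa, pb = pos[partition.labels == la], pos[partition.labels == lb]
            out[(int(la), int(lb))] = {
                "overlap": overlap,
                "mean_distance": float(cdist(pa, pb).mean()),
                "wasserstein": _wasserstein_2d(pa, pb, max_points, seed),
            }
    return out


def checkerboard_regression(
    component_means: np.ndarray,
    square_sizes_cm: np.ndarray,
    size_range_cm: tuple[float, float] = (0.1625, 2.5),
) -> dict:
    """Log-linear regression of a component's mean area on checkerboard
    square size, restricted to the stated spatial-frequency range."""
    y = np.asarray(component_means, dtype=float)
    x = np.asarray(square_sizes_cm, dtype=float)
    sel = (x >= size_range_cm[0]) & (x <= size_range_cm[1])
    if sel.sum() < 4:
        raise ValueError("need >= 4 stimulus levels within the size range")
    res = stats.linregress(np.log(x[sel]), y[sel])
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": int(sel.sum()),
    }
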