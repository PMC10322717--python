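"""Pipeline configuration and stage runner.

A run is a sequence of stages (simulate, segment, features, dynamics,
components, blanching, dimensionality) driven by one validated
:class:`RunConfig`. Every stage writes a machine-readable JSON summary plus
tabular outputs into the run directory, logs every parameter it actually
used, and is deterministic given the config seed. A stage failure aborts the
run with the stage name; outputs of completed stages are preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import blanching as bl
from . import components as comp
from . import dimensionality as dim
from . import dynamics as dyn
from . import imaging as img
from . import synth
from . import texture as tx
from .core import AreaMatrix, ComponentPartition, TrajectoryTruth
from .io import read_area_matrix, read_image_stack, write_area_matrix, write_image_stack, write_partition

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "run_stage", "STAGES"]

STAGES = (
    "simulate",
    "segment",
    "features",
    "dynamics",
    "components",
    "blanching",
    "dimensionality",
)

#: Per-stage defaults; every parameter can be overridden from the config.
STAGE_DEFAULTS: dict[str, dict] = {
    "simulate": {
        "n_chrom": 150,
        "image_size": [384, 384],
        "mean_area_px": 54.0,
        "k_components": 3,
        "n_frames": 300,
        "noise_sd": 0.3,
        "blanch_depth": 0.3,
        "recruitment_order": [2, 0, 1],
        "n_waypoints": 8,
        "heading_noise_sd": 0.25,
        "background_alpha": 2.0,
    },
    "segment": {"min_region_px": 9, "score_threshold": 0.5},
    "features": {"extractor": "bandenergy"},
    "dynamics": {"n_pcs": 200, "smooth_s": 2.0},
    # resolution 1.0 matches the coarse planted-component scale of the demo
    # scene (the 2.0 default of the library targets ~30 components in
    # populations of tens of thousands)
    "components": {"n_pcs": 50, "n_neighbors": 10, "resolution": 1.0},
    "blanching": {"resolution": 0.5, "n_perm": 200},
    "dimensionality": {"n_shuffles": 50, "percentile": 95.0},
}


@dataclass
class RunConfig:
    """Validated run configuration: a seed, stage parameters and paths."""

    seed: int = 0
    out: str = "camopath_run"
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known_top = {"seed", "out", "stages"}
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        stages = raw.get("stages", {}) or {}
        for name, params in stages.items():
            if name not in STAGE_DEFAULTS:
                raise ValueError(f"unknown stage {name!r}")
            bad = set(params or {}) - set(STAGE_DEFAULTS[name])
            if bad:
                raise ValueError(f"unknown parameter(s) for stage {name}: {sorted(bad)}")
        return cls(seed=int(raw.get("seed", 0)), out=str(raw.get("out", "camopath_run")),
                   stages=stages)

    def stage_params(self, name: str) -> dict:
        params = dict(STAGE_DEFAULTS[name])
        params.update(self.stages.get(name, {}) or {})
        return params


def _write_summary(out: Path, stage: str, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    (out / f"{stage}_summary.json").write_text(
        json.dumps(payload, sort_keys=True, indent=1, default=default)
    )


# ------------------------------------------------------------------- stages


def _stage_simulate(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("simulate")
    logger.info("simulate: %s", p)
    seed = cfg.seed
    scene = synth.gen_scene(
        p["n_chrom"], tuple(p["image_size"]), p["mean_area_px"],
        k_components=p["k_components"], seed=seed, layout="interdigitated",
    )
    T = p["n_frames"]
    t = np.arange(T) / 25.0
    K = p["k_components"]
    loadings = np.stack(
        [p["mean_area_px"] * (1.0 + 0.3 * np.sin(2 * np.pi * (0.15 + 0.08 * k) * t + k))
         for k in range(K)]
    )
    am = synth.gen_component_timeseries(scene, T, loadings, p["noise_sd"], seed=seed)
    write_area_matrix(am, out / "areas.csv")
    base = AreaMatrix(np.tile(np.pi * scene.radii**2, (5, 1)))
    stack = synth.render_frames(scene, base)
    write_image_stack(stack, out / "frames.tif")
    bg = synth.gen_background("one_over_f", {"size": (128, 128), "alpha": p["background_alpha"]}, seed=seed)
    np.savetxt(out / "background.csv", bg, delimiter=",")
    truth_traj = TrajectoryTruth(
        "update", start=np.array([0.0, 0.0]), goal=np.array([100.0, 60.0]),
        noise_sd=p["heading_noise_sd"], n_waypoints=p["n_waypoints"], dwell_frames=20,
    )
    traj = synth.gen_transition_trajectory(truth_traj, 800, seed=seed)
    np.savetxt(out / "trajectory.csv", traj.coords, delimiter=",")
    blanch_am, blanch_truth = synth.gen_blanch_trial(
        scene, max(T, 260), p["recruitment_order"], p["blanch_depth"],
        seed=seed, noise_sd=0.01,
    )
    write_area_matrix(blanch_am, out / "blanch_areas.csv")
    truth = {
        "component_labels": scene.component_labels,
        "positions": scene.positions,
        "radii": scene.radii,
        "slow_point_frames": truth_traj.slow_point_frames,
        "blanch": {k: v for k, v in blanch_truth.items()},
        "params": p,
    }
    _write_summary(out, "simulate", truth)
    return {"n_chrom": scene.n_chrom, "k": K}


def _stage_segment(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("segment")
    logger.info("segment: %s", p)
    stack = read_image_stack(out / "frames.tif")
    score = np.stack([img.darkness_score(fr) for fr in stack])
    mean_frame = score.mean(axis=0)
    lm = img.segment_chromatophores(
        mean_frame, None, min_region_px=p["min_region_px"],
        score_threshold=p["score_threshold"],
    )
    areas = img.extract_areas(lm, score)
    write_area_matrix(areas, out / "segmented_areas.csv")
    payload = {"n_regions": lm.n_regions, "params": p,
               "mean_region_area": float(np.mean(list(lm.region_areas.values()) or [0]))}
    _write_summary(out, "segment", payload)
    return payload


def _stage_features(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("features")
    logger.info("features: %s", p)
    bg = np.loadtxt(out / "background.csv", delimiter=",")
    st = tx.texture_stats(bg)
    fv = tx.extract_features(bg, p["extractor"])
    payload = {"texture_stats": st.as_vector(), "feature_len": int(fv.values.size),
               "fft_alpha": st.fft_alpha, "params": p}
    _write_summary(out, "features", payload)
    return payload


def _stage_dynamics(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("dynamics")
    logger.info("dynamics: %s", p)
    coords = np.loadtxt(out / "trajectory.csv", delimiter=",")
    from .core import FeatureTrajectory

    traj = FeatureTrajectory(coords)
    sp = dyn.pattern_speed(traj, n_pcs=p["n_pcs"], smooth=p["smooth_s"])
    slow = dyn.find_slow_points(sp)
    ha = dyn.heading_angles(traj, slow)
    result = {
        "n_slow_points": slow.n_points,
        "slow_indices": slow.indices,
        "params": p,
    }
    if ha.alpha.size >= 5:
        ra = dyn.rayleigh_test(ha.alpha)
        rb = dyn.rayleigh_test(ha.beta)
        result.update(
            alpha_rayleigh={"rbar": ra[0], "z": ra[1], "p": ra[2]},
            beta_rayleigh={"rbar": rb[0], "z": rb[1], "p": rb[2]},
            model=dyn.classify_heading_model(ha),
        )
    _write_summary(out, "dynamics", result)
    return result


def _stage_components(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("components")
    logger.info("components: %s", p)
    am = read_area_matrix(out / "areas.csv")
    part = comp.leiden_components(
        am, n_pcs=p["n_pcs"], n_neighbors=p["n_neighbors"],
        resolution=p["resolution"], seed=cfg.seed,
    )
    write_partition(part, out / "partition.csv")
    truth = json.loads((out / "simulate_summary.json").read_text())
    from sklearn.metrics import adjusted_rand_score

    ari = adjusted_rand_score(truth["component_labels"], part.labels)
    ev = comp.reconstruction_variance(part, am)
    ev_sh = comp.reconstruction_variance(part, am, mode="shuffled", seed=cfg.seed)
    payload = {"k": part.k, "ari_vs_truth": float(ari),
               "explained_variance": ev, "explained_variance_shuffled": ev_sh,
               "params": p}
    _write_summary(out, "components", payload)
    return payload


def _stage_blanching(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("blanching")
    logger.info("blanching: %s", p)
    am = read_area_matrix(out / "blanch_areas.csv")
    selection = bl.select_blanch_trials([am])
    onsets, ranks = bl.recruitment_times(am)
    agg = bl.aggregate_ranks(ranks[None, :])
    rd = bl.rank_density(agg, n_bins=50)
    truth = json.loads((out / "simulate_summary.json").read_text())
    part = ComponentPartition(np.asarray(truth["component_labels"]))
    test = bl.component_rank_test(
        np.where(np.isnan(agg.mu), np.nan, agg.mu), part,
        n_perm=p["n_perm"], seed=cfg.seed,
    )
    order = sorted(test["component_means"], key=test["component_means"].get)
    payload = {
        "selection": {"kept": selection["kept"],
                      "kept_components": selection["kept_components"]},
        "n_recruited": int(np.sum(~np.isnan(onsets))),
        "kruskal_H": test["H"], "kruskal_p": test["p"],
        "recovered_order": [int(o) for o in order],
        "true_order": truth["blanch"]["recruitment_order"],
        "params": p,
    }
    _write_summary(out, "blanching", payload)
    return payload


def _stage_dimensionality(cfg: RunConfig, out: Path) -> dict:
    p = cfg.stage_params("dimensionality")
    logger.info("dimensionality: %s", p)
    am = read_area_matrix(out / "areas.csv")
    res = dim.parallel_analysis(
        am.valid_values(), n_shuffles=p["n_shuffles"],
        percentile=p["percentile"], seed=cfg.seed,
    )
    payload = {"n_significant": res.n_significant,
               "eigenvalues_top10": res.eigenvalues[:10], "params": p}
    _write_summary(out, "dimensionality", payload)
    return payload


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "features": _stage_features,
    "dynamics": _stage_dynamics,
    "components": _stage_components,
    "blanching": _stage_blanching,
    "dimensionality": _stage_dimensionality,
}


def run_stage(cfg: RunConfig, stage: str, out: str | Path | None = None) -> dict:
    """Run one pipeline stage into the run directory."""
    out_dir = Path(out if out is not None else cfg.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stage not in _STAGE_FNS:
        raise ValueError(f"unknown stage {stage!r}")
    return _STAGE_FNS[stage](cfg, out_dir)


def run_pipeline(cfg: RunConfig, out: str | Path | None = None) -> Path:
    """Run every stage in order; deterministic given the config seed.

    A stage failure aborts with the stage name; summaries of completed
    stages are left in place.
    """
    out_dir = Path(out if out is not None else cfg.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setLevel(logging.INFO)
    root = logging.getLogger("camopath")
    root.addHandler(fh)
    try:
        for stage in STAGES:
            logger.info("--- stage %s ---", stage)
            try:
                _STAGE_FNS[stage](cfg, out_dir)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(fh)
        fh.close()
    return out_dir
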