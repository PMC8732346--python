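"""End-to-end pipeline orchestration: simulate -> detect -> track -> disperse.

A :class:`PipelineConfig` (YAML-loadable) drives the stages in dependency
order; every output file is recorded in a JSON manifest with a content hash,
so a rerun with an identical configuration reproduces identical hashes.
A single global seed fans out to the stage generators through fixed
sub-stream offsets, so one integer reproduces a whole run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .delaunay_dispersion import dispersion_score
from .nuclei_detect import DetectionParams, detect_stack, frames_to_csv
from .synthsheet import (
    SimConfig,
    make_lattice,
    render_frame,
    simulate_dispersion,
    write_tiff,
)
from .tracklink import (
    DEFAULT_PAIR_EVAL_MIN,
    average_velocity,
    link_tracks,
    pair_distance_ratio,
    pair_report,
    select_neighbor_pairs,
    trajectory_distance,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "detect", "track", "disperse")


@dataclass
class PipelineConfig:
    """Run-level configuration: stage parameters plus output/seed/logging."""

    sim: SimConfig = field(default_factory=SimConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    max_disp: float = 10.0  # µm, linking gate
    regularity_threshold: float = 0.95
    max_edge: float | None = None
    pair_eval_min: float = DEFAULT_PAIR_EVAL_MIN
    max_pair_dist: float | None = None  # default: 1.5x lattice spacing
    n_pairs: int = 15
    stages: tuple[str, ...] = ALL_STAGES
    out_dir: str = "scatterquant_run"
    log_level: str = "INFO"
    seed: int | None = None  # overrides sim.seed when set

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.seed is not None:
            self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", {})
        if "image_size" in sim:
            sim["image_size"] = tuple(sim["image_size"])
        det = raw.pop("detection", {})
        stages = raw.pop("stages", list(ALL_STAGES))
        return cls(sim=SimConfig(**sim), detection=DetectionParams(**det),
                   stages=tuple(stages), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["image_size"] = list(self.sim.image_size)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest.

    On a stage failure the manifest — recording the stages that completed
    and the files they produced — is still written before the exception
    propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))

    manifest: dict = {
        "scatterquant_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.sim.seed,
        "config": config.to_dict(),
        "completed_stages": [],
        "files": {},
    }

    def record(path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    truth = None
    images = None
    detected = None
    tracks = None
    try:
        if "simulate" in config.stages:
            logger.info("stage simulate: %dx%d lattice, %d frames",
                        config.sim.n_rows, config.sim.n_cols, config.sim.n_frames)
            frame0 = make_lattice(config.sim)
            truth = simulate_dispersion(frame0, config.sim)
            truth.to_csv(out / "truth_tracks.csv")
            record(out / "truth_tracks.csv")
            config.sim.to_yaml(out / "sim_config.yaml")
            record(out / "sim_config.yaml")
            frame_dir = out / "frames"
            frame_dir.mkdir(exist_ok=True)
            images = []
            for fr in truth.frames():
                img = render_frame(fr, config.sim)
                images.append(img)
                p = frame_dir / f"frame_{fr.frame_index:04d}.tif"
                write_tiff(img, p)
                record(p)
            manifest["completed_stages"].append("simulate")

        if "detect" in config.stages:
            if images is None:
                raise RuntimeError("detect stage requires the simulate stage")
            logger.info("stage detect: %d frames", len(images))
            detected = detect_stack(images, config.detection,
                                    pixel_size=config.sim.pixel_size,
                                    frame_interval=config.sim.frame_interval)
            frames_to_csv(detected, out / "centroids.csv")
            record(out / "centroids.csv")
            manifest["completed_stages"].append("detect")

        if "track" in config.stages:
            if detected is None:
                raise RuntimeError("track stage requires the detect stage")
            logger.info("stage track: max_disp=%.2f µm", config.max_disp)
            tracks = link_tracks(detected, max_disp=config.max_disp)
            tracks.to_csv(out / "tracks.csv")
            record(out / "tracks.csv")

            rows = []
            for cid in tracks.cell_ids():
                pts = tracks.points(cid)
                if len(pts) < 2:
                    continue
                rows.append(
                    (cid, trajectory_distance(pts),
                     average_velocity(pts, config.sim.frame_interval))
                )
            pd.DataFrame(
                rows, columns=["cell_id", "trajectory_um", "velocity_um_per_min"]
            ).to_csv(out / "track_metrics.csv", index=False)
            record(out / "track_metrics.csv")

            max_pair = config.max_pair_dist or 1.5 * config.sim.spacing
            pairs = select_neighbor_pairs(detected[0], max_pair, config.n_pairs)
            series = pair_distance_ratio(tracks, pairs, config.pair_eval_min)
            pair_report(series).to_csv(out / "pair_ratios.csv", index=False)
            record(out / "pair_ratios.csv")
            manifest["completed_stages"].append("track")

        if "disperse" in config.stages:
            if detected is None:
                raise RuntimeError("disperse stage requires the detect stage")
            logger.info("stage disperse: regularity >= %.2f",
                        config.regularity_threshold)
            rows = []
            for fr in detected:
                res = dispersion_score(fr, config.regularity_threshold,
                                       config.max_edge)
                rows.append(
                    (fr.frame_index, fr.time_min, res.n_triangles,
                     res.norm_area, res.mean_normalized_area, res.flagged)
                )
            pd.DataFrame(
                rows,
                columns=["frame", "time_min", "n_triangles", "norm_area_um2",
                         "mean_normalized_area", "flagged"],
            ).to_csv(out / "dispersion.csv", index=False)
            record(out / "dispersion.csv")
            manifest["completed_stages"].append("disperse")
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return manifest
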