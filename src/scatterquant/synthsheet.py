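"""Synthetic epithelial-sheet generator.

Produces monolayer nuclear lattices, time-lapse dispersion dynamics with
ground-truth trajectories, rendered fluorescence frames, wound-closure mask
series and expression matrices with planted fold changes.  Every generator is
a pure function of its configuration (including the seed), so identical
configurations give bit-identical output.

Canonical coordinates are micrometres; pixels appear only at the rendering
boundary.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

#: Column order used for every centroid / track CSV written by the package.
TRACK_CSV_COLUMNS = ["frame", "time_min", "cell_id", "x_um", "y_um"]

# Sub-stream offsets for fanning a single SimConfig seed out to the
# independent generators (lattice jitter, motion noise, camera noise, ...).
_STREAM_LATTICE = 0
_STREAM_MOTION = 1
_STREAM_RENDER = 2
_STREAM_EXPRESSION = 3


class InvalidParameterError(ValueError):
    """A configuration value violates its documented invariant."""


@dataclass(frozen=True)
class SimConfig:
    """All parameters of the synthetic monolayer / time-lapse generator.

    Defaults mirror the imaging regime the pipeline targets: a cobblestone
    sheet of ~20 µm inter-nuclear spacing imaged at 10-min intervals for
    20 h with a 10x objective (0.65 µm/px camera sampling).

    Parameters
    ----------
    n_rows, n_cols : int
        Lattice extent (cells).
    spacing : float
        Triangular-lattice edge length, µm.
    jitter_sd : float
        Isotropic Gaussian perturbation of lattice sites, µm.
    n_frames : int
        Total number of frames, including frame 0.
    frame_interval : float
        Time between frames, minutes.
    diffusion_sd : float
        Per-frame isotropic random-walk step, µm.
    drift_rate : float
        Per-frame radial (outward from the initial cloud centroid) step, µm.
    image_size : (int, int)
        Rendered frame shape, (height, width) pixels.
    pixel_size : float
        µm per pixel.
    spot_sigma : float
        Gaussian nuclear-spot sd, pixels.
    peak_intensity : float
        Spot peak height, arbitrary units.
    noise_sd : float
        Additive Gaussian camera noise sd, arbitrary units.
    seed : int
        Master seed; all sub-generators derive from it deterministically.
    """

    n_rows: int = 12
    n_cols: int = 12
    spacing: float = 20.0
    jitter_sd: float = 1.0
    n_frames: int = 120
    frame_interval: float = 10.0
    diffusion_sd: float = 0.2
    drift_rate: float = 0.0
    image_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.65
    spot_sigma: float = 2.0
    peak_intensity: float = 1000.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise InvalidParameterError("spacing must be > 0")
        if self.jitter_sd < 0:
            raise InvalidParameterError("jitter_sd must be >= 0")
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be > 0")
        if self.drift_rate < 0:
            raise InvalidParameterError("drift_rate must be >= 0")
        if self.diffusion_sd < 0:
            raise InvalidParameterError("diffusion_sd must be >= 0")
        if self.n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")

    def rng(self, stream: int, *extra: int) -> np.random.Generator:
        """Deterministic sub-generator for one named noise source."""
        return np.random.default_rng([self.seed, stream, *extra])

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["image_size"] = list(self.image_size)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        return cls(**d)


@dataclass
class CentroidFrame:
    """Nuclear centres of one time point, in µm."""

    frame_index: int
    time_min: float
    points: np.ndarray  # (n, 2) float, columns x_um, y_um
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("centroid coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    def min_separation(self) -> float:
        if len(self.points) < 2:
            return np.inf
        return float(pdist(self.points).min())


@dataclass
class TruthTracks:
    """Ground-truth trajectories: every cell present in every frame."""

    df: pd.DataFrame  # columns frame, time_min, cell_id, x_um, y_um
    pixel_size: float = 1.0

    def n_cells(self) -> int:
        return self.df["cell_id"].nunique()

    def n_frames(self) -> int:
        return self.df["frame"].nunique()

    def positions(self, frame: int) -> np.ndarray:
        sub = self.df[self.df["frame"] == frame].sort_values("cell_id")
        return sub[["x_um", "y_um"]].to_numpy()

    def frames(self) -> list[CentroidFrame]:
        """Re-emit as per-frame centroid clouds (identity stripped)."""
        out = []
        for f, sub in self.df.groupby("frame", sort=True):
            sub = sub.sort_values("cell_id")
            out.append(
                CentroidFrame(
                    frame_index=int(f),
                    time_min=float(sub["time_min"].iloc[0]),
                    points=sub[["x_um", "y_um"]].to_numpy(),
                    pixel_size=self.pixel_size,
                )
            )
        return out

    def to_csv(self, path: str | Path) -> None:
        self.df[TRACK_CSV_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Lattice


def make_lattice(config: SimConfig, min_separation: float = 1e-6) -> CentroidFrame:
    """Jittered triangular ("hexagonal-packing") lattice of nuclear centres.

    Even rows sit at x = c*spacing, odd rows are offset by spacing/2, and row
    pitch is spacing*sqrt(3)/2, so at zero jitter every nearest-neighbour
    distance equals ``spacing`` and the Delaunay triangles are congruent
    equilateral triangles.  The sheet is centred on the physical centre of
    the configured field of view.
    """
    if config.n_rows < 2 or config.n_cols < 2:
        raise InvalidParameterError("n_rows and n_cols must both be >= 2")
    r = np.arange(config.n_rows)
    c = np.arange(config.n_cols)
    cc, rr = np.meshgrid(c, r)
    x = cc * config.spacing + (rr % 2) * (config.spacing / 2.0)
    y = rr * (config.spacing * np.sqrt(3.0) / 2.0)
    pts = np.column_stack([x.ravel(), y.ravel()]).astype(float)

    # centre the sheet in the field of view (µm)
    h, w = config.image_size
    field_center = np.array([w * config.pixel_size / 2.0, h * config.pixel_size / 2.0])
    pts += field_center - pts.mean(axis=0)

    rng = config.rng(_STREAM_LATTICE)
    if config.jitter_sd > 0:
        jitter = rng.normal(0.0, config.jitter_sd, size=pts.shape)
        for _ in range(100):
            cand = pts + jitter
            if len(cand) < 2 or pdist(cand).min() >= min_separation:
                break
            jitter = rng.normal(0.0, config.jitter_sd, size=pts.shape)
        else:
            raise InvalidParameterError(
                "could not place jittered lattice with the requested minimum "
                "separation; reduce jitter_sd or min_separation"
            )
        pts = cand

    return CentroidFrame(frame_index=0, time_min=0.0, points=pts,
                         pixel_size=config.pixel_size)


# ---------------------------------------------------------------------------
# Time-lapse dynamics


def simulate_dispersion(frame0: CentroidFrame, config: SimConfig) -> TruthTracks:
    """Radial-drift + diffusion time-lapse of a nuclear point cloud.

    Each frame, every point advances ``drift_rate`` µm along the unit vector
    from the *initial* cloud centroid to its current position (cells at the
    sheet edge separate outward, mimicking nest dispersion), plus isotropic
    Gaussian diffusion of sd ``diffusion_sd``.  With zero diffusion a point
    initially at radius r sits at exactly r + k*drift_rate after k frames.
    """
    if len(frame0) == 0:
        raise InvalidParameterError("frame0 must contain at least one point")
    rng = config.rng(_STREAM_MOTION)
    center = frame0.points.mean(axis=0)
    pos = frame0.points.copy()
    n = len(pos)
    cell_ids = np.arange(n)

    records = [
        pd.DataFrame(
            {"frame": 0, "time_min": 0.0, "cell_id": cell_ids,
             "x_um": pos[:, 0], "y_um": pos[:, 1]}
        )
    ]
    for k in range(1, config.n_frames):
        vec = pos - center
        norm = np.linalg.norm(vec, axis=1, keepdims=True)
        unit = np.divide(vec, norm, out=np.zeros_like(vec), where=norm > 1e-12)
        pos = pos + config.drift_rate * unit
        if config.diffusion_sd > 0:
            pos = pos + rng.normal(0.0, config.diffusion_sd, size=pos.shape)
        records.append(
            pd.DataFrame(
                {"frame": k, "time_min": k * config.frame_interval,
                 "cell_id": cell_ids, "x_um": pos[:, 0], "y_um": pos[:, 1]}
            )
        )
    df = pd.concat(records, ignore_index=True)
    return TruthTracks(df=df, pixel_size=config.pixel_size)


# ---------------------------------------------------------------------------
# Rendering


class PointOutOfFieldError(ValueError):
    """Raised when centroids fall outside the rendered field of view."""

    def __init__(self, indices: np.ndarray):
        self.indices = list(map(int, indices))
        super().__init__(
            f"points outside the field of view at indices {self.indices}"
        )


def render_frame(frame: CentroidFrame, config: SimConfig) -> np.ndarray:
    """Render a centroid cloud as a noisy fluorescence image.

    The image is a sum of isotropic 2-D Gaussians (sd ``spot_sigma`` px,
    height ``peak_intensity``) evaluated at pixel centres — pixel (i, j)
    covers [j, j+1) x [i, i+1) with centre (j+0.5, i+0.5) — plus additive
    Gaussian noise, clipped to be nonnegative.
    """
    h, w = config.image_size
    pts_px = frame.points / config.pixel_size
    bad = np.nonzero(
        (pts_px[:, 0] < 0) | (pts_px[:, 0] >= w)
        | (pts_px[:, 1] < 0) | (pts_px[:, 1] >= h)
    )[0]
    if bad.size:
        raise PointOutOfFieldError(bad)

    img = np.zeros((h, w), dtype=float)
    sig = config.spot_sigma
    half = max(1, int(np.ceil(6 * sig)))
    xc = np.arange(w) + 0.5
    yc = np.arange(h) + 0.5
    for x, y in pts_px:
        j0, j1 = max(0, int(x) - half), min(w, int(x) + half + 1)
        i0, i1 = max(0, int(y) - half), min(h, int(y) + half + 1)
        gx = np.exp(-((xc[j0:j1] - x) ** 2) / (2 * sig**2))
        gy = np.exp(-((yc[i0:i1] - y) ** 2) / (2 * sig**2))
        img[i0:i1, j0:j1] += config.peak_intensity * np.outer(gy, gx)

    if config.noise_sd > 0:
        rng = config.rng(_STREAM_RENDER, frame.frame_index)
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def write_tiff(image: np.ndarray, path: str | Path) -> None:
    """Save an intensity image as 16-bit single-channel TIFF."""
    data = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


# ---------------------------------------------------------------------------
# Wound fixtures


def make_wound_series(
    width0: float,
    closure_per_frame: float,
    n_frames: int,
    image_size: tuple[int, int] = (128, 128),
    pixel_size: float = 1.0,
) -> list[np.ndarray]:
    """Binary wound-assay masks: a vertical cell-free band closing linearly.

    Mask value 1 = cell-covered.  The gap at frame k has width
    max(0, width0 - k*closure_per_frame) µm, centred in the field.
    """
    if width0 <= 0:
        raise InvalidParameterError("width0 must be > 0")
    h, w = image_size
    xc = (np.arange(w) + 0.5) * pixel_size
    mid = w * pixel_size / 2.0
    masks = []
    for k in range(n_frames):
        gap = max(0.0, width0 - k * closure_per_frame)
        mask = np.ones((h, w), dtype=np.uint8)
        mask[:, np.abs(xc - mid) < gap / 2.0] = 0
        masks.append(mask)
    return masks


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (linear scale, strictly positive)."""

    values: pd.DataFrame  # index genes, columns samples
    conditions: Mapping[str, str]  # sample -> condition label
    truth: pd.DataFrame | None = None  # planted per-gene, per-condition FC

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("expression values must be strictly positive")
        missing = set(self.values.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.values.columns if self.conditions[s] == condition]
        if not out:
            raise KeyError(f"no samples with condition {condition!r}")
        return out

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.columns = [f"{s}:{self.conditions[s]}" for s in out.columns]
        out.to_csv(path, index_label="gene")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExpressionMatrix":
        raw = pd.read_csv(path, index_col=0, sep=None, engine="python")
        samples, conditions = [], {}
        for col in raw.columns:
            name, _, cond = col.partition(":")
            if not cond:
                raise ValueError(
                    f"column {col!r} lacks a ':condition' suffix"
                )
            samples.append(name)
            conditions[name] = cond
        raw.columns = samples
        return cls(values=raw, conditions=conditions)


def simulate_expression(
    n_genes: int,
    conditions: Mapping[str, int] | Sequence[str],
    planted: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
) -> ExpressionMatrix:
    """Expression matrix with planted condition fold changes.

    Per gene, a baseline log2 level is drawn once; samples of a condition in
    which the gene is planted get log2(fold change) added, plus per-sample
    Gaussian noise of sd ``noise_sd`` (log2 units).  At zero noise the
    measured fold change of a planted gene equals the planted value exactly.

    Parameters
    ----------
    conditions
        Either a mapping condition -> number of replicate samples, or a
        sequence of condition labels (one sample each).
    planted
        Mapping gene id -> {condition: fold change}; fold changes are
        relative to the gene's baseline and must be positive.  Gene ids are
        ``g0000``, ``g0001``, ...
    """
    if not isinstance(conditions, Mapping):
        conditions = {c: 1 for c in conditions}
    planted = planted or {}
    genes = [f"g{i:04d}" for i in range(n_genes)]
    gene_set = set(genes)
    for g, fcs in planted.items():
        if g not in gene_set:
            raise InvalidParameterError(f"planted gene {g!r} not in matrix")
        for cond, fc in fcs.items():
            if cond not in conditions:
                raise InvalidParameterError(f"unknown condition {cond!r}")
            if fc <= 0:
                raise InvalidParameterError("planted fold changes must be > 0")

    rng = np.random.default_rng([seed, _STREAM_EXPRESSION])
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)

    sample_names, sample_conditions = [], {}
    for cond, n_rep in conditions.items():
        for r in range(n_rep):
            name = f"{cond}_{r + 1}" if n_rep > 1 else cond
            sample_names.append(name)
            sample_conditions[name] = cond

    log2fc = pd.DataFrame(0.0, index=genes, columns=list(conditions))
    for g, fcs in planted.items():
        for cond, fc in fcs.items():
            log2fc.loc[g, cond] = np.log2(fc)

    data = {}
    for name in sample_names:
        cond = sample_conditions[name]
        log2 = baseline + log2fc[cond].to_numpy()
        if noise_sd > 0:
            log2 = log2 + rng.normal(0.0, noise_sd, size=n_genes)
        data[name] = np.exp2(log2)
    values = pd.DataFrame(data, index=genes)

    truth = log2fc.rename(columns=lambda c: c).apply(np.exp2)
    return ExpressionMatrix(values=values, conditions=sample_conditions, truth=truth)
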