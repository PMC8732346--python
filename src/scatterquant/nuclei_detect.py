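"""Nuclear centroid detection from fluorescence images.

A classical particle-analysis pipeline: Gaussian smoothing, global
thresholding (Otsu or fixed), 4-connected component labelling, an inclusive
area window, and intensity-weighted centroids reported in µm.

Coordinate convention: pixel (i, j) covers the unit square with centre
(j + 0.5, i + 0.5); centroids are reported at physical positions, i.e.
(col + 0.5) * pixel_size and (row + 0.5) * pixel_size.  This matches the
rendering convention of :mod:`scatterquant.synthsheet`, so detection on a
noiseless render recovers the generating coordinates to sub-pixel accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

from .synthsheet import CentroidFrame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Particle-analysis settings.

    ``min_area``/``max_area`` (px²) are an inclusive window: components with
    area exactly at either bound are kept.  ``threshold_method`` is ``otsu``
    (default; intensity-scale invariant) or ``fixed`` (requires
    ``fixed_threshold``).
    """

    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area: int = 4
    max_area: int = 10_000
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        if not 0 <= self.min_area < self.max_area:
            raise ValueError("need 0 <= min_area < max_area")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


def detect_centroids(
    image: np.ndarray,
    params: DetectionParams = DetectionParams(),
    pixel_size: float = 1.0,
    frame_index: int = 0,
    time_min: float = 0.0,
) -> CentroidFrame:
    """Detect nuclear centres in a 2-D single-channel image.

    Returns an empty frame (not an error) when nothing crosses the
    threshold, e.g. on an all-zero image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if image.min() < 0:
        raise ValueError("image intensities must be nonnegative")

    if params.smoothing_sigma > 0:
        smoothed = gaussian(image, sigma=params.smoothing_sigma,
                            preserve_range=True)
    else:
        smoothed = image

    if params.threshold_method == "otsu":
        if np.ptp(smoothed) == 0:  # flat image: nothing to segment
            return CentroidFrame(frame_index, time_min,
                                 np.empty((0, 2)), pixel_size)
        thresh = threshold_otsu(smoothed)
    else:
        thresh = float(params.fixed_threshold)  # type: ignore[arg-type]

    mask = smoothed > thresh
    labels = label(mask, connectivity=1)  # 4-connected
    pts = []
    for region in regionprops(labels, intensity_image=smoothed):
        if not params.min_area <= region.area <= params.max_area:
            continue
        row, col = region.centroid_weighted
        pts.append(((col + 0.5) * pixel_size, (row + 0.5) * pixel_size))

    pts_arr = np.array(pts, dtype=float).reshape(-1, 2)
    logger.debug("detected %d centroids (threshold=%.3g)", len(pts_arr), thresh)
    return CentroidFrame(frame_index, time_min, pts_arr, pixel_size)


def detect_stack(
    images: list[np.ndarray],
    params: DetectionParams = DetectionParams(),
    pixel_size: float = 1.0,
    frame_interval: float = 10.0,
) -> list[CentroidFrame]:
    """Run detection over an ordered image stack."""
    return [
        detect_centroids(img, params, pixel_size,
                         frame_index=k, time_min=k * frame_interval)
        for k, img in enumerate(images)
    ]


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF or PNG as a float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(str(path)), dtype=float)
    import imageio.v3 as iio

    return np.asarray(iio.imread(str(path)), dtype=float)


def frames_to_csv(frames: list[CentroidFrame], path: str | Path) -> None:
    """Write detected frames in the package's track CSV layout (point index
    stands in for cell_id; identities come later from linking)."""
    rows = []
    for fr in frames:
        for i, (x, y) in enumerate(fr.points):
            rows.append((fr.frame_index, fr.time_min, i, x, y))
    pd.DataFrame(
        rows, columns=["frame", "time_min", "cell_id", "x_um", "y_um"]
    ).to_csv(path, index=False)


def frames_from_csv(path: str | Path, pixel_size: float = 1.0) -> list[CentroidFrame]:
    """Load per-frame centroid clouds from a track-layout CSV."""
    df = pd.read_csv(path)
    out = []
    for f, sub in df.groupby("frame", sort=True):
        out.append(
            CentroidFrame(
                frame_index=int(f),
                time_min=float(sub["time_min"].iloc[0]),
                points=sub[["x_um", "y_um"]].to_numpy(),
                pixel_size=pixel_size,
            )
        )
    return out
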