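"""Delaunay-triangulation dispersion scoring of nuclear point clouds.

The dispersion statistic rests on a geometric premise: a cobblestone
epithelial sheet has near-uniform inter-nuclear distances, so its Delaunay
triangulation consists of near-equilateral ("regular") triangles.  When
cells disperse, triangles grow and deform.  Each plot is therefore
normalised by its own regular triangles:

1. Delaunay-triangulate the nuclear centres.
2. Score every triangle's shape regularity  q = 4*sqrt(3)*A / (l1²+l2²+l3²),
   which is 1 exactly for equilateral triangles and tends to 0 for slivers.
3. The triangles with q >= regularity_threshold form the regular set; the
   normalisation constant is their mean area.
4. The dispersion score is the mean of area / norm_area over all retained
   triangles — 1.0 for an undisturbed sheet, > 1 as the sheet disperses.

The score is dimensionless and invariant under translation, rotation and
uniform scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .synthsheet import CentroidFrame
from . import stats_report

logger = logging.getLogger(__name__)

DEFAULT_REGULARITY_THRESHOLD = 0.95


class DegenerateInputError(ValueError):
    """Fewer than three points, or all points collinear."""


@dataclass
class DispersionResult:
    """Triangulation-level dispersion readout for one point cloud."""

    triangles: np.ndarray  # (m, 3) vertex indices
    areas: np.ndarray  # µm²
    regularity: np.ndarray  # in (0, 1]
    norm_area: float  # µm², mean area of the regular set
    mean_normalized_area: float  # the dispersion score
    n_triangles: int
    regularity_threshold: float
    max_edge: float | None
    flagged: bool = False  # True when no triangle met the regularity threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v0": self.triangles[:, 0],
                "v1": self.triangles[:, 1],
                "v2": self.triangles[:, 2],
                "area_um2": self.areas,
                "regularity": self.regularity,
                "normalized_area": self.areas / self.norm_area,
            }
        )


def triangulate(frame: CentroidFrame) -> np.ndarray:
    """Delaunay triangulation of a centroid cloud; (m, 3) vertex indices.

    Exactly degenerate triangles (zero area, e.g. from collinear subsets on
    the hull) are dropped; an entirely collinear or too-small input raises
    :class:`DegenerateInputError`.
    """
    pts = frame.points
    if len(pts) < 3:
        raise DegenerateInputError("need at least 3 points to triangulate")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateInputError(f"degenerate point set: {exc}") from exc
    simplices = tri.simplices
    areas = triangle_areas(pts, simplices)
    keep = areas > 0
    if not keep.any():
        raise DegenerateInputError("all triangles degenerate (collinear points)")
    return simplices[keep]


def triangle_areas(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Vectorised unsigned triangle areas."""
    p = points[triangles]  # (m, 3, 2)
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    return 0.5 * np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])


def triangle_regularity(vertices: np.ndarray) -> float:
    """Shape regularity of one triangle: 4*sqrt(3)*A / sum of squared edges.

    Equals 1 iff equilateral; approaches 0 as the triangle degenerates.
    A zero-area triangle is an error.
    """
    v = np.asarray(vertices, dtype=float).reshape(3, 2)
    a, b = v[1] - v[0], v[2] - v[0]
    area = 0.5 * abs(a[0] * b[1] - a[1] * b[0])
    if area == 0:
        raise ValueError("regularity undefined for a zero-area triangle")
    edges_sq = (
        np.sum((v[1] - v[0]) ** 2)
        + np.sum((v[2] - v[1]) ** 2)
        + np.sum((v[0] - v[2]) ** 2)
    )
    return float(4.0 * np.sqrt(3.0) * area / edges_sq)


def _regularities(points: np.ndarray, triangles: np.ndarray,
                  areas: np.ndarray) -> np.ndarray:
    p = points[triangles]
    edges_sq = (
        np.sum((p[:, 1] - p[:, 0]) ** 2, axis=1)
        + np.sum((p[:, 2] - p[:, 1]) ** 2, axis=1)
        + np.sum((p[:, 0] - p[:, 2]) ** 2, axis=1)
    )
    return 4.0 * np.sqrt(3.0) * areas / edges_sq


def dispersion_score(
    frame: CentroidFrame,
    regularity_threshold: float = DEFAULT_REGULARITY_THRESHOLD,
    max_edge: float | None = None,
) -> DispersionResult:
    """Mean regular-triangle-normalised Delaunay area of a nuclear cloud.

    Parameters
    ----------
    regularity_threshold
        Triangles with regularity at or above this value define the
        normalisation constant (their mean area).
    max_edge
        Optional µm cutoff: triangles with any edge longer than this are
        dropped before scoring.  Useful to suppress huge convex-hull
        slivers; a common choice is ~3x the median edge length.

    If no triangle reaches the regularity threshold, the median of all
    retained areas is used as the normalisation constant instead and the
    result is flagged.
    """
    triangles = triangulate(frame)
    pts = frame.points

    if max_edge is not None:
        p = pts[triangles]
        edge_len = np.stack(
            [
                np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
                np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
                np.linalg.norm(p[:, 0] - p[:, 2], axis=1),
            ],
            axis=1,
        )
        keep = edge_len.max(axis=1) <= max_edge
        dropped = int((~keep).sum())
        if dropped:
            logger.info("max_edge=%g dropped %d/%d triangles",
                        max_edge, dropped, len(triangles))
        triangles = triangles[keep]
        if len(triangles) == 0:
            raise DegenerateInputError("max_edge filter removed every triangle")

    areas = triangle_areas(pts, triangles)
    regularity = _regularities(pts, triangles, areas)

    regular = regularity >= regularity_threshold
    flagged = not regular.any()
    if flagged:
        norm_area = float(np.median(areas))
        logger.warning(
            "no triangle met regularity >= %.3g; falling back to the median "
            "area (%.4g µm²) as the normalisation constant",
            regularity_threshold, norm_area,
        )
    else:
        norm_area = float(areas[regular].mean())

    return DispersionResult(
        triangles=triangles,
        areas=areas,
        regularity=regularity,
        norm_area=norm_area,
        mean_normalized_area=float((areas / norm_area).mean()),
        n_triangles=len(triangles),
        regularity_threshold=regularity_threshold,
        max_edge=max_edge,
        flagged=flagged,
    )


def compare_conditions(
    scores_by_group: dict[str, list[float]],
) -> pd.DataFrame:
    """ANOVA + Tukey post hoc over per-image dispersion scores by condition.

    ``scores_by_group`` maps a condition label to its per-image
    mean-normalised-area values.  Returns a tidy table combining the omnibus
    one-way ANOVA row with one row per Tukey pairwise comparison.
    """
    if len(scores_by_group) < 2:
        raise ValueError("need at least two groups to compare")
    for label, vals in scores_by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {label!r} needs >= 2 observations")
    anova = stats_report.one_way_anova(scores_by_group)
    tukey = stats_report.tukey_hsd(scores_by_group)
    rows = [
        {
            "comparison": "omnibus",
            "test": "one-way ANOVA",
            "statistic": anova.statistic,
            "df": str(anova.df),
            "p_value": anova.p_value,
            "stars": anova.stars,
        }
    ]
    for pair in tukey:
        rows.append(
            {
                "comparison": f"{pair.groups[0]} vs {pair.groups[1]}",
                "test": "Tukey HSD",
                "statistic": pair.statistic,
                "df": str(pair.df),
                "p_value": pair.p_value,
                "stars": pair.stars,
            }
        )
    return pd.DataFrame(rows)
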