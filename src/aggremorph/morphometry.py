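"""Per-aggregate morphometry: length, eccentricity, intensity, rendering.

Eccentricity follows the ellipse convention: for semi-axes a >= b,
e = sqrt(1 - b^2/a^2), i.e. the focal distance divided by the major axis.
It is recovered here from the second central moments of the localization
cloud (eigenvalues lam1 >= lam2 give e = sqrt(1 - lam2/lam1)), which for a
uniform elliptical sample equals the boundary-ellipse value without any
boundary fit.  A perfect circle scores 0; collinear clouds score exactly 1
(fibrillar morphology).

Length is, by default, the maximum pairwise distance between member
localizations (max Feret diameter) — robust and monotone under adding
points.  The projection extent along the major axis is available as an
alternative metric.  Localization noise inflates both raw measures by a
few tens of nm at sigma_loc ~ 20 nm; no bias correction is applied by
default because raw measurements are what the assay reports, but an
optional correction subtracting a 2*sigma_loc-scale inflation can be
switched on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .clustering import ClusterLabeling

__all__ = [
    "MorphometryRecord",
    "SampleSummary",
    "measure_cluster",
    "records_to_frame",
    "render_superres",
    "summarize_sample",
]


@dataclass
class MorphometryRecord:
    """Measured properties of one aggregate (one cluster of localizations)."""

    cluster_id: int
    n_locs: int
    length: float               # nm
    eccentricity: float         # in [0, 1]
    total_intensity: float
    centroid: tuple[float, float]
    major_axis_angle: float     # radians


@dataclass
class SampleSummary:
    """Per-sample aggregate statistics (one field of view / one run)."""

    n_clusters: int
    median_length: float
    mean_length: float
    mean_eccentricity: float
    per_fov_count: int
    no_clusters: bool = False


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Max Feret diameter; convex-hull reduction for larger clouds."""
    n = points.shape[0]
    if n > 60:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (collinear) cloud: fall through to pairwise
    return float(pdist(points).max())


def measure_cluster(
    points: np.ndarray,
    intensities: np.ndarray | None = None,
    cluster_id: int = 0,
    length_metric: str = "feret",
    sigma_loc_correction: float = 0.0,
) -> MorphometryRecord:
    """Measure one cluster of localization positions (nm).

    Parameters
    ----------
    length_metric:
        ``"feret"`` (default) for the maximum pairwise distance, or
        ``"extent"`` for max - min of the projections onto the major axis.
    sigma_loc_correction:
        If > 0, subtract ``2 * sigma_loc_correction`` from the raw length
        (floored at 0) to offset localization-noise inflation.  Off (0) by
        default: raw measurements are reported.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 2:
        raise ValueError("measure_cluster needs at least 2 points of shape (n, 2)")
    n = points.shape[0]
    if intensities is None:
        intensities = np.zeros(n)
    intensities = np.asarray(intensities, dtype=float)
    if intensities.shape[0] != n:
        raise ValueError("intensities must match the number of points")

    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = centered.T @ centered / n
    eigvals, eigvecs = np.linalg.eigh(cov)      # ascending
    lam2, lam1 = float(eigvals[0]), float(eigvals[1])
    lam2 = max(lam2, 0.0)
    if lam1 <= 0.0:                              # all points coincident
        ecc, angle = 0.0, 0.0
        length = 0.0
    else:
        ecc = math.sqrt(max(0.0, 1.0 - lam2 / lam1))
        major = eigvecs[:, 1]
        angle = math.atan2(major[1], major[0]) % math.pi
        if length_metric == "feret":
            length = _max_pairwise_distance(points)
        elif length_metric == "extent":
            proj = centered @ major
            length = float(proj.max() - proj.min())
        else:
            raise ValueError("length_metric must be 'feret' or 'extent'")
    if sigma_loc_correction > 0.0:
        length = max(0.0, length - 2.0 * sigma_loc_correction)
    return MorphometryRecord(
        cluster_id=cluster_id,
        n_locs=n,
        length=length,
        eccentricity=ecc,
        total_intensity=float(intensities.sum()),
        centroid=(float(centroid[0]), float(centroid[1])),
        major_axis_angle=angle,
    )


def summarize_sample(
    table: pd.DataFrame,
    labeling: ClusterLabeling,
    length_metric: str = "feret",
    sigma_loc_correction: float = 0.0,
) -> tuple[list[MorphometryRecord], SampleSummary]:
    """Measure every non-noise cluster of a localization table.

    Returns the per-aggregate records plus sample-level summary statistics
    (median/mean length, mean eccentricity, cluster count).  A labeling
    with no clusters yields an empty list and a summary flagged
    ``no_clusters`` with zeroed statistics rather than NaNs.
    """
    if len(table) != labeling.labels.size:
        raise ValueError("labeling does not match the localization table length")
    records: list[MorphometryRecord] = []
    xy = table[["x", "y"]].to_numpy()
    inten = table["intensity"].to_numpy()
    for cid in range(labeling.n_clusters):
        members = np.nonzero(labeling.labels == cid)[0]
        records.append(
            measure_cluster(
                xy[members],
                inten[members],
                cluster_id=cid,
                length_metric=length_metric,
                sigma_loc_correction=sigma_loc_correction,
            )
        )
    if records:
        lengths = np.array([r.length for r in records])
        eccs = np.array([r.eccentricity for r in records])
        summary = SampleSummary(
            n_clusters=len(records),
            median_length=float(np.median(lengths)),
            mean_length=float(lengths.mean()),
            mean_eccentricity=float(eccs.mean()),
            per_fov_count=len(records),
        )
    else:
        summary = SampleSummary(0, 0.0, 0.0, 0.0, 0, no_clusters=True)
    return records, summary


def records_to_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    """Morphometry records as a DataFrame in the documented CSV column order."""
    return pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in records],
            "n_locs": [r.n_locs for r in records],
            "length_nm": [r.length for r in records],
            "eccentricity": [r.eccentricity for r in records],
            "total_intensity": [r.total_intensity for r in records],
            "centroid_x_nm": [r.centroid[0] for r in records],
            "centroid_y_nm": [r.centroid[1] for r in records],
            "angle_rad": [r.major_axis_angle for r in records],
        }
    )


def render_superres(
    table: pd.DataFrame,
    pixel: float,
    blur_sigma: float,
    fov_size: float | None = None,
) -> np.ndarray:
    """Reconstruct a super-resolution image from a localization table.

    A 2D histogram of localizations at ``pixel`` nm per pixel, convolved
    with a unit-mass Gaussian of SD ``blur_sigma`` nm, so the image
    integral equals the number of (in-field) localizations up to kernel
    truncation at the image edges.  Row index is y (origin at the bottom),
    column index is x.
    """
    if pixel <= 0:
        raise ValueError("pixel must be > 0")
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    x = table["x"].to_numpy()
    y = table["y"].to_numpy()
    if fov_size is None:
        fov_size = float(max(x.max(), y.max())) + pixel if len(table) else pixel
    n_px = int(np.ceil(fov_size / pixel))
    edges = np.arange(n_px + 1) * pixel
    hist, _, _ = np.histogram2d(y, x, bins=(edges, edges))
    if blur_sigma > 0:
        hist = gaussian_filter(hist, sigma=blur_sigma / pixel, mode="constant")
    return hist
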