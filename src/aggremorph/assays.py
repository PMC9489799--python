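"""Toxicity read-out quantifications: dye influx and spot counting.

The membrane-permeabilization read-out images the same liposome field
under three conditions (background, sample, ionophore) and scores each
liposome by

    influx% = 100 * (F_sample - F_background) / (F_ionomycin - F_background)

where F is the spot's fluorescence intensity under each condition.  The
ratio is invariant under any affine rescaling v -> alpha*v + gamma of the
intensities (alpha > 0), so camera gain and offset cancel.  Values are
deliberately *not* clamped to [0, 100]: noise produces small negatives,
and clamping would bias field-of-view means.

The pulldown / diffraction-limited counting read-out thresholds spot
intensities against a negative control: the threshold is the smallest
intensity at which the mean control count per field drops to a budget,
and target/control count ratios quantify assay specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

__all__ = [
    "FieldCount",
    "InfluxMeasurement",
    "average_frames",
    "calibrate_threshold",
    "compute_influx",
    "count_spots",
    "detect_spots",
    "match_spots",
    "normalize_response",
    "specificity_ratio",
]


@dataclass
class InfluxMeasurement:
    """Per-liposome intensities under the three conditions and the influx %."""

    spot_id: int
    position: tuple[float, float]   # nm
    F_background: float
    F_sample: float
    F_ionomycin: float
    influx_pct: float
    valid: bool


@dataclass
class FieldCount:
    """Spot count of one field of view at a given intensity threshold."""

    fov_id: int
    condition: str
    threshold: float
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")


def average_frames(stack: np.ndarray) -> np.ndarray:
    """Per-pixel arithmetic mean across the frames of a stack."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("average_frames needs a stack with >= 1 frame")
    return stack.mean(axis=0)


def detect_spots(
    image: np.ndarray,
    pixel_size: float,
    min_distance_px: int = 2,
    threshold_k: float = 5.0,
    window_half: int = 2,
    measure: str = "integrated",
) -> list[tuple[tuple[float, float], float]]:
    """Find bright spots in an averaged image and measure their intensity.

    Spots are local maxima above (median + threshold_k * robust noise SD).
    Intensity is, by default, the background-subtracted sum over a
    (2*window_half+1)^2 window ("integrated"); ``measure="peak"`` uses the
    background-subtracted maximum pixel instead.  Returns a list of
    ((x, y) in nm, intensity) pairs.
    """
    image = np.asarray(image, dtype=float)
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    noise = 1.4826 * mad
    peaks = peak_local_max(
        image,
        min_distance=min_distance_px,
        threshold_abs=med + threshold_k * max(noise, 1e-12),
        exclude_border=window_half,
    )
    spots = []
    for pi, pj in peaks:
        window = image[pi - window_half: pi + window_half + 1,
                       pj - window_half: pj + window_half + 1]
        if measure == "integrated":
            intensity = float(window.sum() - window.size * med)
        elif measure == "peak":
            intensity = float(window.max() - med)
        else:
            raise ValueError("measure must be 'integrated' or 'peak'")
        x = (pj + 0.5) * pixel_size
        y = (pi + 0.5) * pixel_size
        spots.append(((x, y), intensity))
    return spots


def match_spots(
    spots_background: list[tuple[tuple[float, float], float]],
    spots_sample: list[tuple[tuple[float, float], float]],
    spots_ionomycin: list[tuple[tuple[float, float], float]],
    radius: float = 474.0,
) -> tuple[list[tuple[tuple[float, float], float, float, float]], int]:
    """Mutual nearest-neighbour matching of spots across the three conditions.

    The default radius is two diffraction-limited pixels (474 nm).  A
    background spot is kept only when it and its nearest sample and
    ionophore spots are each other's mutual nearest neighbours within the
    radius.  Returns (triplets as (position, F_b, F_s, F_i), number of
    unmatched background spots).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")

    def _arr(spots):
        if not spots:
            return np.empty((0, 2)), np.empty(0)
        pos = np.array([p for p, _ in spots], dtype=float)
        inten = np.array([v for _, v in spots], dtype=float)
        return pos, inten

    pb, ib = _arr(spots_background)
    ps, is_ = _arr(spots_sample)
    pi_, ii = _arr(spots_ionomycin)
    triplets = []
    unmatched = 0
    if len(pb) == 0 or len(ps) == 0 or len(pi_) == 0:
        return [], len(pb)
    ts, ti, tb = cKDTree(ps), cKDTree(pi_), cKDTree(pb)
    for k in range(pb.shape[0]):
        ok = True
        partners = {}
        for tree, pos_other, name in ((ts, ps, "s"), (ti, pi_, "i")):
            d, j = tree.query(pb[k])
            if d > radius:
                ok = False
                break
            # mutual: the partner's nearest background spot must be k
            db, jb = tb.query(pos_other[j])
            if jb != k:
                ok = False
                break
            partners[name] = j
        if not ok:
            unmatched += 1
            continue
        triplets.append(
            (
                (float(pb[k, 0]), float(pb[k, 1])),
                float(ib[k]),
                float(is_[partners["s"]]),
                float(ii[partners["i"]]),
            )
        )
    return triplets, unmatched


def compute_influx(
    triplets: list[tuple[tuple[float, float], float, float, float]],
) -> tuple[list[InfluxMeasurement], float]:
    """Per-spot influx percentages and their field-of-view mean.

    Spots whose ionophore response does not exceed the background
    (F_ionomycin <= F_background) are flagged invalid and excluded from
    the mean; if every spot is invalid the field has no responsive
    liposomes and an error is raised.
    """
    if not triplets:
        raise ValueError("compute_influx needs a non-empty triplet list")
    measurements: list[InfluxMeasurement] = []
    valid_pcts = []
    for sid, (pos, fb, fs, fi) in enumerate(triplets):
        if not all(math.isfinite(v) for v in (fb, fs, fi)):
            raise ValueError("intensities must be finite")
        valid = fi > fb
        pct = 100.0 * (fs - fb) / (fi - fb) if valid else float("nan")
        measurements.append(
            InfluxMeasurement(sid, pos, fb, fs, fi, pct, valid)
        )
        if valid:
            valid_pcts.append(pct)
    if not valid_pcts:
        raise ValueError("no responsive liposomes in this field of view")
    return measurements, float(np.mean(valid_pcts))


def calibrate_threshold(
    control_counts_by_threshold: dict[float, float], budget: float = 2.0
) -> float:
    """Smallest threshold whose mean negative-control count per field <= budget.

    The input maps candidate intensity thresholds to the mean spot count
    per field of view observed in the negative control; counts must be
    monotone non-increasing in the threshold.
    """
    if not control_counts_by_threshold:
        raise ValueError("no candidate thresholds given")
    items = sorted(control_counts_by_threshold.items())
    counts = [c for _, c in items]
    if any(b > a + 1e-9 for a, b in zip(counts, counts[1:])):
        raise ValueError("control counts must be non-increasing in threshold")
    for threshold, count in items:
        if count <= budget:
            return threshold
    raise ValueError(
        f"budget {budget} unreachable; minimal achievable mean count is {counts[-1]}"
    )


def count_spots(
    image: np.ndarray,
    threshold: float,
    pixel_size: float = 237.0,
    fov_id: int = 0,
    condition: str = "",
    measure: str = "integrated",
) -> FieldCount:
    """Count detected spots whose intensity exceeds ``threshold``.

    All local maxima are detected first (independently of the threshold)
    and then filtered, so the count is exactly monotone non-increasing in
    the threshold.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    spots = detect_spots(image, pixel_size=pixel_size, measure=measure)
    n = sum(1 for _, intensity in spots if intensity > threshold)
    return FieldCount(fov_id=fov_id, condition=condition,
                      threshold=threshold, count=n)


def specificity_ratio(
    target_counts: list[float], control_counts: list[float]
) -> tuple[float, float]:
    """mean(target)/mean(control) spot-count ratio, with a dispersion estimate.

    A zero control mean yields an infinite ratio (flagged as ``math.inf``).
    The dispersion is the ratio's SD from independent per-field
    fluctuations by first-order error propagation.
    """
    if not target_counts or not control_counts:
        raise ValueError("both count lists must be non-empty")
    t = np.asarray(target_counts, dtype=float)
    c = np.asarray(control_counts, dtype=float)
    if c.mean() == 0:
        return math.inf, math.nan
    ratio = t.mean() / c.mean()
    rel_t = t.std(ddof=1) / (t.mean() * math.sqrt(t.size)) if t.size > 1 and t.mean() else 0.0
    rel_c = c.std(ddof=1) / (c.mean() * math.sqrt(c.size)) if c.size > 1 else 0.0
    return float(ratio), float(abs(ratio) * math.hypot(rel_t, rel_c))


def normalize_response(
    values: list[float] | np.ndarray, neg_mean: float, pos_mean: float
) -> np.ndarray:
    """Map raw responses onto a 0-100% scale between control means.

    0% corresponds to the negative control (buffer) mean and 100% to the
    positive control mean: v -> 100 * (v - neg) / (pos - neg).
    """
    if not pos_mean > neg_mean:
        raise ValueError("pos_mean must exceed neg_mean")
    values = np.asarray(values, dtype=float)
    return 100.0 * (values - neg_mean) / (pos_mean - neg_mean)
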