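"""Quantify stained calibrator bead images into per-spot intensity summaries.

The chain mirrors how calibrator slides are read in practice: convert the RGB
photomicrograph to greyscale, segment circular beads with a Hough transform
restricted to the plausible radius range, drop overlapping (mis-segmented)
detections, measure each bead's chromogen signal as the dot product of its
background-subtracted RGB values with the unit DAB stain profile, assign
beads to their spots, and summarise spot mean/SD.  Duplicate slides are
averaged spot-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import canny
from skimage.draw import disk
from skimage.transform import hough_circle, hough_circle_peaks

from .synthetic import DAB_RGB, SpotLayout

__all__ = [
    "BeadDetection",
    "SpotSummary",
    "to_greyscale",
    "detect_beads",
    "remove_overlaps",
    "stain_intensity",
    "assign_spots",
    "summarize_spots",
    "average_duplicates",
    "quantify_image",
]

#: Rec. 709-style luminance weights, matching scikit-image's rgb2gray.
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class BeadDetection:
    """One segmented bead: centre (x, y) in pixels, radius, Hough score."""

    x: float
    y: float
    radius: float
    accumulator: float
    stain_intensity: float = np.nan
    spot_id: int | None = None


@dataclass
class SpotSummary:
    """Per-spot bead statistics.

    ``concentration`` is in molecules (ERF) per cell-equivalent and NaN for
    negative-control spots (``is_negative``).
    """

    spot_id: int
    concentration: float
    is_negative: bool
    n_beads: int
    mean_intensity: float
    sd_intensity: float


def to_greyscale(rgb_image: np.ndarray) -> np.ndarray:
    """Luminance-weighted greyscale conversion, preserving the input scale.

    Accepts 3-channel 8- or 16-bit (or float) images; anything without
    exactly three channels is rejected.
    """
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 image")
    return img.astype(float) @ _LUMA


def detect_beads(
    grey_image: np.ndarray,
    radius_range: tuple[int, int] = (5, 8),
    *,
    canny_sigma: float = 1.2,
    edge_low: float = 0.005,
    edge_high: float = 0.02,
    peak_threshold: float = 0.5,
    min_accumulator: float = 0.3,
    max_value: float = 255.0,
) -> list[BeadDetection]:
    """Segment circular beads with a circle Hough transform.

    Edges come from a Canny detector with permissive thresholds (faint
    negative-control beads have only a few percent contrast against the
    background); the Hough accumulator is scanned over every integer radius
    in ``radius_range`` and peaks below ``peak_threshold`` of the global
    maximum -- or below the absolute floor ``min_accumulator``, the fraction
    of a circle's perimeter that must be supported by edge pixels -- are
    discarded.  Detections whose radius falls outside the
    allowable range are dropped -- with integer scan radii this means the
    range bounds act as a hard gate on what can be returned.
    """
    r_min, r_max = radius_range
    if not 0 < r_min < r_max:
        raise ValueError("radius_range must satisfy 0 < r_min < r_max")
    grey = np.asarray(grey_image, dtype=float)
    if grey.ndim != 2:
        raise ValueError("expected a single-channel image")
    if grey.size == 0 or grey.std() == 0:
        return []
    edges = canny(grey / max_value, sigma=canny_sigma,
                  low_threshold=edge_low, high_threshold=edge_high)
    if not edges.any():
        return []
    radii = np.arange(r_min, r_max + 1)
    accumulator = hough_circle(edges, radii)
    accums, cx, cy, rad = hough_circle_peaks(
        accumulator, radii,
        min_xdistance=r_min * 2, min_ydistance=r_min * 2,
        threshold=max(peak_threshold * accumulator.max(), min_accumulator),
        total_num_peaks=np.inf,
    )
    found = [
        BeadDetection(x=float(x), y=float(y), radius=float(r), accumulator=float(a))
        for a, x, y, r in zip(accums, cx, cy, rad)
        if r_min <= r <= r_max
    ]
    # peak separation is enforced within each radius slice only, so the same
    # bead can fire at several radii; keep the strongest per location
    found.sort(key=lambda c: (-c.accumulator, c.y, c.x))
    kept: list[BeadDetection] = []
    for cand in found:
        if all(np.hypot(cand.x - k.x, cand.y - k.y) >= r_min for k in kept):
            kept.append(cand)
    return kept


def remove_overlaps(
    circles: list[BeadDetection], tolerance: float = 1.0
) -> list[BeadDetection]:
    """Drop overlapping detections, keeping the strongest accumulator.

    Two circles conflict when their centre distance is below
    ``tolerance * (r1 + r2)``.  Greedy rule: visit circles in decreasing
    accumulator order (ties broken by y then x for determinism) and keep a
    circle only if it conflicts with nothing already kept.
    """
    order = sorted(circles, key=lambda c: (-c.accumulator, c.y, c.x))
    kept: list[BeadDetection] = []
    for cand in order:
        ok = True
        for k in kept:
            d = np.hypot(cand.x - k.x, cand.y - k.y)
            if d < tolerance * (cand.radius + k.radius):
                ok = False
                break
        if ok:
            kept.append(cand)
    return kept


def stain_intensity(
    rgb_image: np.ndarray,
    circle: BeadDetection,
    dab_profile: np.ndarray = DAB_RGB,
    *,
    background: float = 255.0,
    erode: int = 1,
    max_sample_radius: float | None = None,
) -> float:
    """Mean chromogen signal over a bead's interior pixels.

    The per-pixel signal is ``background - RGB`` (so more chromogen means a
    larger value) projected onto the unit DAB profile.  The sampling disk is
    shrunk by ``erode`` pixels to stay clear of the bead boundary, where
    segmentation may be off by a pixel, and optionally capped at
    ``max_sample_radius`` so that a detection fitted to the outside of a
    bead's rim still samples pure interior.
    """
    profile = np.asarray(dab_profile, dtype=float)
    if profile.shape != (3,):
        raise ValueError("dab_profile must be a 3-vector")
    img = np.asarray(rgb_image, dtype=float)
    h, w = img.shape[:2]
    r = circle.radius
    if not (r <= circle.x <= w - 1 - r and r <= circle.y <= h - 1 - r):
        raise ValueError("circle extends outside the image")
    sample_r = r - erode
    if max_sample_radius is not None:
        sample_r = min(sample_r, max_sample_radius)
    rr, cc = disk((circle.y, circle.x), max(sample_r, 1.0), shape=(h, w))
    signal = background - img[rr, cc]
    return float((signal @ profile).mean())


def assign_spots(
    circles: list[BeadDetection], layout: SpotLayout
) -> list[BeadDetection]:
    """Assign each bead to the nearest spot centre within the spot radius.

    Beads outside every spot are discarded (they are segmentation artefacts
    by construction of the slide layout).
    """
    centers = np.asarray(layout.spot_centers(), dtype=float)
    kept = []
    for c in circles:
        d = np.hypot(centers[:, 0] - c.x, centers[:, 1] - c.y)
        nearest = int(np.argmin(d))
        if d[nearest] <= layout.spot_radius:
            c.spot_id = nearest
            kept.append(c)
    return kept


def summarize_spots(
    detections: list[BeadDetection], layout: SpotLayout
) -> pd.DataFrame:
    """Mean/SD of bead stain intensity per spot.

    Spots with no assigned beads are flagged (``n_beads = 0`` row with NaN
    statistics) rather than silently dropped; downstream consumers decide
    whether an empty spot invalidates the slide.
    """
    table = layout.spot_table()
    rows = []
    for spot in table.itertuples(index=False):
        vals = np.array([d.stain_intensity for d in detections
                         if d.spot_id == spot.spot_id])
        n = vals.size
        rows.append({
            "spot_id": spot.spot_id,
            "concentration": spot.concentration,
            "is_negative": spot.is_negative,
            "n_beads": int(n),
            "mean_intensity": float(vals.mean()) if n else np.nan,
            "sd_intensity": float(vals.std(ddof=1)) if n > 1 else (0.0 if n else np.nan),
        })
    return pd.DataFrame(rows)


def average_duplicates(run1: pd.DataFrame, run2: pd.DataFrame) -> pd.DataFrame:
    """Average two duplicate slide measurements spot-wise.

    Spot means (and SDs) are combined as plain arithmetic means, the
    convention for duplicate calibrator readings; bead counts are summed.
    The operation is symmetric in its arguments.
    """
    if not (run1["spot_id"] == run2["spot_id"]).all():
        raise ValueError("duplicate runs must share the spot layout")
    out = run1.copy()
    out["mean_intensity"] = (run1["mean_intensity"].to_numpy()
                             + run2["mean_intensity"].to_numpy()) / 2.0
    out["sd_intensity"] = (run1["sd_intensity"].to_numpy()
                           + run2["sd_intensity"].to_numpy()) / 2.0
    out["n_beads"] = run1["n_beads"].to_numpy() + run2["n_beads"].to_numpy()
    return out


def quantify_image(
    rgb_image: np.ndarray,
    layout: SpotLayout = SpotLayout(),
    radius_range: tuple[int, int] = (5, 8),
    dab_profile: np.ndarray = DAB_RGB,
) -> pd.DataFrame:
    """Full quantification chain for one slide image -> spot summary table."""
    grey = to_greyscale(rgb_image)
    circles = detect_beads(grey, radius_range)
    circles = remove_overlaps(circles)
    circles = assign_spots(circles, layout)
    for c in circles:
        c.stain_intensity = stain_intensity(
            rgb_image, c, dab_profile, max_sample_radius=radius_range[0])
    return summarize_spots(circles, layout)
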