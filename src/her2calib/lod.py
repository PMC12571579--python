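"""Lower limit of detection (LOD) from calibrator spot summaries.

The analytic response of a chromogenic IHC assay on the calibrator ladder is
sigmoid when stain intensity is plotted against concentration on linear axes:
a baseline where nothing is detected, a rising region, and a saturation
plateau.  The rising region is well described by ``y = a ln(x) + b``.  The
LOD (in the limit-of-blank sense) is the concentration whose predicted
intensity equals the negative-control mean plus three negative-control SDs:

    LOD = exp((y* - b) / a),   y* = neg_mean + 3 * neg_sd

Baseline points (intensity no greater than the negative-control mean) and
plateau points are excluded from the fit; at least three points must remain.
LODs below the lowest calibrator concentration are legitimate extrapolations
and are flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bead_quant
from .synthetic import SpotLayout

__all__ = [
    "ResponseCurve",
    "LODEstimate",
    "InsufficientSlopePoints",
    "classify_points",
    "fit_log_regression",
    "compute_lod",
    "estimate_lod",
    "lod_from_images",
]

#: Minimum number of rising-region points required for a log regression.
MIN_SLOPE_POINTS = 3


class InsufficientSlopePoints(ValueError):
    """Raised when fewer than three points remain on the rising region."""


@dataclass
class ResponseCurve:
    """Labelled calibrator response: one label per (concentration, intensity).

    ``labels`` take values in {"baseline", "slope", "plateau"}.
    """

    concentrations: np.ndarray
    intensities: np.ndarray
    neg_mean: float
    neg_sd: float
    labels: np.ndarray

    def slope_points(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.labels == "slope"
        return self.concentrations[m], self.intensities[m]


@dataclass
class LODEstimate:
    """Result of the LOD calculation for one laboratory slide (pair)."""

    a: float                    # intensity per ln(concentration)
    b: float                    # intercept
    r_squared: float
    y_star: float               # neg_mean + 3 * neg_sd
    lod: float                  # molecules (ERF) per cell-equivalent
    n_points_used: int
    extrapolated_below_lowest: bool


def classify_points(
    concentrations: np.ndarray,
    intensities: np.ndarray,
    neg_mean: float,
    neg_sd: float,
    plateau_fraction: float = 0.05,
    baseline_tolerance: float = 0.0,
    saturation_tolerance: float = 0.0,
) -> ResponseCurve:
    """Label calibrator points as baseline, slope or plateau.

    Baseline: intensity no greater than the negative-control mean (the
    comparison deliberately uses the mean alone, not the +3 SD threshold).
    ``baseline_tolerance`` widens the comparison by a measurement-uncertainty
    margin: a spot mean within that margin of the negative mean is
    indistinguishable from baseline and must not enter the log fit, where its
    huge residual would corrupt the line.  Callers set it from the standard
    error of the spot means (see :func:`estimate_lod`); it is a numerical
    guard, orders of magnitude below the +3 SD detection threshold.
    Plateau: the largest suffix of at least two points whose consecutive
    intensity increments all stay below ``plateau_fraction`` of the observed
    dynamic span (max minus min over all points and the negative mean).  The
    increment rule cannot see a *single* saturating point at the top of the
    ladder (its increment from the last rising point is still large), so a
    second pass trims the tail: while the highest remaining point falls below
    the log-line fitted to the rising set by more than
    ``saturation_tolerance``, it is relabelled plateau.  Whatever remains,
    which is contiguous for a monotone response, is the rising region used
    for regression.
    """
    conc = np.asarray(concentrations, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if conc.size < 4:
        raise ValueError("need at least 4 calibrator points")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if neg_sd < 0:
        raise ValueError("neg_sd must be >= 0")

    labels = np.array(["slope"] * conc.size, dtype=object)
    labels[inten <= neg_mean + baseline_tolerance] = "baseline"

    span = max(inten.max(), neg_mean) - min(inten.min(), neg_mean)
    if span > 0:
        i = conc.size - 1
        while i > 0 and abs(inten[i] - inten[i - 1]) < plateau_fraction * span:
            i -= 1
        if i < conc.size - 1:  # suffix of >= 2 points is flat
            labels[i:] = "plateau"

    # trim a saturating tail the increment rule cannot detect
    while (labels == "slope").sum() > MIN_SLOPE_POINTS:
        idx = np.flatnonzero(labels == "slope")
        a, b, _ = fit_log_regression(conc[idx], inten[idx])
        last = idx[-1]
        resid = inten[last] - (a * np.log(conc[last]) + b)
        if resid < -max(saturation_tolerance, 1e-9):
            labels[last] = "plateau"
        else:
            break
    return ResponseCurve(conc, inten, float(neg_mean), float(neg_sd),
                         labels.astype(str))


def fit_log_regression(
    concentrations: np.ndarray, intensities: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares fit of ``intensity = a ln(concentration) + b``.

    Returns ``(a, b, r_squared)``.  Requires at least three points with
    distinct concentrations.
    """
    x = np.log(np.asarray(concentrations, dtype=float))
    y = np.asarray(intensities, dtype=float)
    if x.size < MIN_SLOPE_POINTS:
        raise InsufficientSlopePoints(
            f"log regression needs >= {MIN_SLOPE_POINTS} points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("all concentrations equal: singular design")
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return float(a), float(b), r2


def compute_lod(a: float, b: float, y_star: float,
                lowest_concentration: float | None = None) -> tuple[float, bool]:
    """Invert the fitted line at the detection threshold intensity.

    ``lod = exp((y_star - b) / a)``; a non-positive slope means the slide has
    no interpretable response and is rejected.  When the solution falls below
    the lowest calibrator concentration the estimate is an extrapolation of
    the fitted rising region and is flagged.
    """
    if a <= 0:
        raise ValueError("non-positive slope: no interpretable response")
    lod = float(np.exp((y_star - b) / a))
    extrapolated = (lowest_concentration is not None
                    and lod < lowest_concentration)
    return lod, extrapolated


def estimate_lod(
    spot_summary: pd.DataFrame,
    plateau_fraction: float = 0.05,
) -> LODEstimate:
    """LOD from one spot-summary table (as built by :mod:`bead_quant`).

    Negative-control statistics pool the per-spot means weighted by bead
    count into a single mean, and use the bead-count-weighted mean of the
    per-spot SDs for the spread, so a dropped bead in one spot cannot skew
    the threshold.
    """
    neg = spot_summary[spot_summary["is_negative"] & (spot_summary["n_beads"] > 0)]
    pos = spot_summary[~spot_summary["is_negative"] & (spot_summary["n_beads"] > 0)]
    if neg.empty:
        raise ValueError("no negative-control measurements")
    w = neg["n_beads"].to_numpy(dtype=float)
    neg_mean = float(np.average(neg["mean_intensity"], weights=w))
    neg_sd = float(np.average(neg["sd_intensity"], weights=w))
    pos = pos.sort_values("concentration")

    # spots whose mean is within ~3 standard errors of the negative mean are
    # indistinguishable from baseline
    sem = (pos["sd_intensity"] / np.sqrt(pos["n_beads"])).to_numpy()
    baseline_tol = 3.0 * float(np.median(sem))
    curve = classify_points(pos["concentration"].to_numpy(),
                            pos["mean_intensity"].to_numpy(),
                            neg_mean, neg_sd, plateau_fraction,
                            baseline_tolerance=baseline_tol,
                            saturation_tolerance=baseline_tol)
    conc_s, inten_s = curve.slope_points()
    if conc_s.size < MIN_SLOPE_POINTS:
        raise InsufficientSlopePoints(
            f"only {conc_s.size} points on the rising region")
    a, b, r2 = fit_log_regression(conc_s, inten_s)
    y_star = neg_mean + 3.0 * neg_sd
    lod, extrapolated = compute_lod(
        a, b, y_star, lowest_concentration=float(pos["concentration"].min()))
    return LODEstimate(a=a, b=b, r_squared=r2, y_star=y_star, lod=lod,
                       n_points_used=int(conc_s.size),
                       extrapolated_below_lowest=extrapolated)


def lod_from_images(
    image_run1: np.ndarray,
    image_run2: np.ndarray | None = None,
    layout: SpotLayout = SpotLayout(),
    plateau_fraction: float = 0.05,
) -> LODEstimate:
    """End-to-end LOD for one laboratory: image(s) -> spots -> estimate.

    Measurements are performed in duplicate when a second image is supplied
    and averaged spot-wise before estimation.
    """
    run1 = bead_quant.quantify_image(image_run1, layout)
    if image_run2 is not None:
        run2 = bead_quant.quantify_image(image_run2, layout)
        summary = bead_quant.average_duplicates(run1, run2)
    else:
        summary = run1
    return estimate_lod(summary, plateau_fraction)
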