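"""Assay dynamic range: regression of aggregate HER2 score on sensitivity.

An assay has dynamic range in the HER2-low region when scores respond to
analytic sensitivity: grouping laboratories into LOD bins (centre +/- 5,000
molecules per cell-equivalent), the aggregate consensus TMA score per bin
should fall as LOD rises.  The slope of the ordinary least-squares line of
aggregate score on bin centre measures that response; a slope of zero means
the scores do not react to sensitivity at all.  Slopes are tested against
zero, and against each other, with t statistics.

Orientation note: sensitivity *increases* as LOD decreases, so a working
dynamic range shows up as a *negative* fitted slope in LOD units; magnitudes
are compared as absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import consensus as cns

__all__ = [
    "LODBin",
    "SlopeResult",
    "bin_labs",
    "aggregate_by_bin",
    "dynamic_range_slope",
    "compare_slopes",
    "per_score_fractions",
]

DEFAULT_BIN_CENTERS = (10_000, 20_000, 30_000, 40_000, 50_000, 60_000)
DEFAULT_HALFWIDTH = 5_000.0


@dataclass
class LODBin:
    """Labs within ``halfwidth`` of an LOD centre (inclusive bounds).

    Adjacent bins may share labs when centres are closer than twice the
    halfwidth; overlapping windows are permitted.
    """

    center: float
    halfwidth: float
    member_labs: list[str] = field(default_factory=list)

    @property
    def n_labs(self) -> int:
        return len(self.member_labs)


@dataclass
class SlopeResult:
    """OLS slope of aggregate score on LOD bin centre, with its t test."""

    slope: float              # score units per molecule/cell-equivalent
    intercept: float
    se_slope: float
    t_statistic: float
    p_value: float
    n_points: int
    domain_restriction: float | None = None

    @property
    def df(self) -> int:
        return self.n_points - 2


def bin_labs(
    labs: pd.DataFrame,
    centers=DEFAULT_BIN_CENTERS,
    halfwidth: float = DEFAULT_HALFWIDTH,
) -> list[LODBin]:
    """Group labs into LOD bins by the absolute-difference rule."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    centers = sorted(float(c) for c in centers)
    bins = []
    for c in centers:
        members = labs.loc[(labs["true_lod"] - c).abs() <= halfwidth, "lab_id"]
        bins.append(LODBin(center=c, halfwidth=halfwidth,
                           member_labs=list(members)))
    return bins


def aggregate_by_bin(
    bins: list[LODBin],
    score_matrix: pd.DataFrame,
    labs: pd.DataFrame,
    include_ultralow: bool,
    readout: str,
) -> pd.DataFrame:
    """Aggregate consensus TMA score per non-empty bin, one readout at a time.

    Mixing readouts inside one regression is disallowed by design: the two
    readout arms have different noise structure and the comparison between
    them is the analysis of interest.
    """
    if readout not in ("manual", "image_analysis"):
        raise ValueError("readout must be 'manual' or 'image_analysis'")
    arm = set(labs.loc[labs["readout"] == readout, "lab_id"])
    rows = []
    for b in bins:
        members = [lab for lab in b.member_labs if lab in arm]
        if not members:
            continue
        agg = cns.average_tma_score(score_matrix, members, include_ultralow)
        rows.append({"center": b.center, "aggregate_score": agg,
                     "n_labs": len(members)})
    return pd.DataFrame(rows)


def _ols(x: np.ndarray, y: np.ndarray) -> SlopeResult:
    if x.size < 3:
        raise ValueError("need at least 3 bin points for a slope")
    res = stats.linregress(x, y)
    if res.stderr > 0:
        t = res.slope / res.stderr
        p = 2.0 * stats.t.sf(abs(t), x.size - 2)
    else:  # perfect fit: slope exactly determined
        t = np.inf if res.slope != 0 else 0.0
        p = 0.0 if res.slope != 0 else 1.0
    return SlopeResult(slope=float(res.slope), intercept=float(res.intercept),
                       se_slope=float(res.stderr), t_statistic=float(t),
                       p_value=float(p), n_points=int(x.size))


def dynamic_range_slope(
    bins: list[LODBin],
    score_matrix: pd.DataFrame,
    labs: pd.DataFrame,
    include_ultralow: bool = True,
    readout: str = "image_analysis",
    domain_restriction: float | None = None,
) -> SlopeResult:
    """Dynamic-range slope for one readout arm.

    ``domain_restriction`` keeps only bins with centre strictly below the
    given LOD before fitting (used when a visible breakpoint makes the upper
    range a separate regime).
    """
    pts = aggregate_by_bin(bins, score_matrix, labs, include_ultralow, readout)
    if domain_restriction is not None:
        pts = pts[pts["center"] < domain_restriction]
    result = _ols(pts["center"].to_numpy(dtype=float),
                  pts["aggregate_score"].to_numpy(dtype=float))
    result.domain_restriction = domain_restriction
    return result


def compare_slopes(result_a: SlopeResult, result_b: SlopeResult) -> float:
    """Two-sided p for equality of two independent regression slopes.

    t = (b1 - b2) / sqrt(se1^2 + se2^2) with Welch-Satterthwaite degrees of
    freedom from the two residual dfs.  Symmetric in its arguments.
    """
    v1, v2 = result_a.se_slope**2, result_b.se_slope**2
    if v1 == 0 and v2 == 0:
        return 1.0 if result_a.slope == result_b.slope else 0.0
    if result_a.df <= 0 or result_b.df <= 0:
        raise ValueError("degenerate regression: se undefined")
    t = (result_a.slope - result_b.slope) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / result_a.df + v2**2 / result_b.df)
    return float(2.0 * stats.t.sf(abs(t), df))


def per_score_fractions(
    bins: list[LODBin],
    score_matrix: pd.DataFrame,
    labs: pd.DataFrame,
    include_ultralow: bool = True,
    readout: str = "image_analysis",
) -> tuple[pd.DataFrame, dict[float, SlopeResult]]:
    """Fraction of cores at each consensus score level per bin, with trends.

    Returns the per-bin fraction table (fractions sum to 1 within each bin)
    and, per score level, the OLS regression of that level's fraction on the
    bin centre.  The HER2 0 fraction is the one that tracks sensitivity even
    under manual readout: less sensitive assays leave more cores scoreless.
    """
    levels = cns.SCORE_LEVELS if include_ultralow else cns.STANDARD_LEVELS
    arm = set(labs.loc[labs["readout"] == readout, "lab_id"])
    rows = []
    for b in bins:
        members = [lab for lab in b.member_labs if lab in arm]
        if not members:
            continue
        cons = cns.consensus_scores(score_matrix, members, include_ultralow)
        n = len(cons)
        for lv in levels:
            frac = float((cons["rounded_score"] == lv).sum()) / n
            rows.append({"center": b.center, "score_level": lv, "fraction": frac})
    table = pd.DataFrame(rows)
    trends = {}
    for lv in levels:
        sub = table[table["score_level"] == lv]
        trends[lv] = _ols(sub["center"].to_numpy(dtype=float),
                          sub["fraction"].to_numpy(dtype=float))
    return table, trends
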