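"""Consensus HER2 scores over laboratory subsets, with the survey's rounding.

The gold standard for HER2-low has no reference assay, so analyses use the
*consensus* of a group of laboratories selected by analytic sensitivity: the
per-core mean score over the group, rounded to the nearest valid HER2 score.
Worked examples of the rounding convention: a mean of 1.7 rounds to 2+; a
mean of 0.7 rounds *down* to 0.5 when the ultralow category is in play and
*up* to 1+ when it is not (0.7 is nearer 0.5 than 1, and nearer 1 than 0).
Exact midpoints round down to the lower score.

When the ultralow category is excluded, ultralow (0.5) laboratory scores are
tabulated as HER2 0 before averaging -- that is how the standard scoring
guidelines treat faint staining -- and the rounding target set is {0,1,2,3}.
"""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SCORE_LEVELS

__all__ = [
    "STANDARD_LEVELS",
    "LabCriterion",
    "round_to_score",
    "select_labs",
    "consensus_scores",
    "average_tma_score",
]

#: Rounding targets when the ultralow category is excluded.
STANDARD_LEVELS = (0.0, 1.0, 2.0, 3.0)


def round_to_score(mean_score: float, include_ultralow: bool = True) -> float:
    """Round a per-core mean to the nearest valid HER2 score, ties down.

    With ``include_ultralow`` the target set is {0, 0.5, 1, 2, 3}; without
    it, {0, 1, 2, 3}.
    """
    levels = np.asarray(SCORE_LEVELS if include_ultralow else STANDARD_LEVELS)
    d = np.abs(levels - float(mean_score))
    return float(levels[int(np.argmin(d))])  # argmin takes the lower on ties


@dataclass(frozen=True)
class LabCriterion:
    """Selection rule over laboratory metadata.

    Exactly one of the constructors applies:

    * ``LabCriterion.interval(lo, hi)`` -- LOD in [lo, hi], both inclusive;
    * ``LabCriterion.lod_above(x)`` / ``lod_below(x)`` -- strict one-sided
      bounds, matching the "> 40,000" / "< 20,000" phrasing of mismatch
      scenarios;
    * ``LabCriterion.assay(name)`` -- assay-label equality.

    A readout restriction may be stacked on any of them.
    """

    predicate: Callable[[pd.DataFrame], pd.Series]
    description: str
    readout: str | None = None

    @staticmethod
    def interval(lo: float, hi: float, readout: str | None = None) -> "LabCriterion":
        return LabCriterion(
            lambda labs: (labs["true_lod"] >= lo) & (labs["true_lod"] <= hi),
            f"LOD in [{lo:g}, {hi:g}]", readout)

    @staticmethod
    def lod_above(x: float, readout: str | None = None) -> "LabCriterion":
        return LabCriterion(lambda labs: labs["true_lod"] > x,
                            f"LOD > {x:g}", readout)

    @staticmethod
    def lod_below(x: float, readout: str | None = None) -> "LabCriterion":
        return LabCriterion(lambda labs: labs["true_lod"] < x,
                            f"LOD < {x:g}", readout)

    @staticmethod
    def assay(name: str, readout: str | None = None) -> "LabCriterion":
        return LabCriterion(lambda labs: labs["assay"] == name,
                            f"assay = {name}", readout)

    def mask(self, labs: pd.DataFrame) -> pd.Series:
        m = self.predicate(labs)
        if self.readout is not None:
            m = m & (labs["readout"] == self.readout)
        return m


def select_labs(labs: pd.DataFrame, criterion: LabCriterion) -> pd.DataFrame:
    """Labs satisfying the criterion; an empty selection is an error."""
    sel = labs[criterion.mask(labs)]
    if sel.empty:
        raise ValueError(f"no labs match criterion: {criterion.description}")
    return sel


def _validate_scores(scores: pd.Series) -> None:
    valid = set(SCORE_LEVELS)
    bad = set(scores.unique()) - valid
    if bad:
        raise ValueError(f"scores outside the valid set {sorted(valid)}: {sorted(bad)}")


def consensus_scores(
    matrix: pd.DataFrame,
    lab_subset: pd.DataFrame | list[str],
    include_ultralow: bool = True,
) -> pd.DataFrame:
    """Per-core consensus over a lab subset.

    Returns one row per core with ``mean_score`` (continuous), the
    ``rounded_score`` under the active rounding set, and ``n_labs``.  Cores
    never scored by any subset lab are excluded (reported via absence); an
    empty subset is rejected.
    """
    lab_ids = (lab_subset["lab_id"] if isinstance(lab_subset, pd.DataFrame)
               else pd.Series(list(lab_subset)))
    if len(lab_ids) == 0:
        raise ValueError("empty lab subset")
    sub = matrix[matrix["lab_id"].isin(set(lab_ids))]
    if sub.empty:
        raise ValueError("no scores from the selected labs")
    _validate_scores(sub["score"])
    score = sub["score"].to_numpy(dtype=float)
    if not include_ultralow:
        score = np.where(score == 0.5, 0.0, score)
    sub = sub.assign(score=score)
    g = sub.groupby("core_id")["score"].agg(["mean", "count"]).reset_index()
    g = g.rename(columns={"mean": "mean_score", "count": "n_labs"})
    g["rounded_score"] = [round_to_score(m, include_ultralow)
                          for m in g["mean_score"]]
    return g[["core_id", "mean_score", "rounded_score", "n_labs"]]


def average_tma_score(
    matrix: pd.DataFrame,
    lab_subset: pd.DataFrame | list[str],
    include_ultralow: bool = True,
) -> float:
    """Aggregate TMA score: mean of the per-core *rounded* consensus scores.

    Consensus first, then average -- the aggregate a dynamic-range analysis
    plots against analytic sensitivity.  Missing cores are excluded rather
    than imputed.
    """
    cons = consensus_scores(matrix, lab_subset, include_ultralow)
    return float(cons["rounded_score"].mean())
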