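"""Diagnostic accuracy: ISH gold standard, treatment rules, LOD mismatch.

Two accuracy questions are answered here.  For HER2 over-expression
(Trastuzumab eligibility) the gold standard is gene amplification by in situ
hybridisation: a HER2/CEP17 ratio of at least 2.  For HER2-low (T-Dxd
eligibility) no reference assay exists, so the gold standard is the rounded
consensus of a laboratory group selected by LOD, mapped through a treatment
rule; each laboratory's own calls are then scored against that standard.
Confusion counts feed sensitivity, specificity, predictive values and
accuracy = (TN + TP) / (TN + FP + FN + TP), each with an exact
Clopper-Pearson binomial confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import consensus as cns
from .consensus import LabCriterion
from .synthetic import SCORE_LEVELS

__all__ = [
    "ConfusionCounts",
    "DiagnosticMetrics",
    "TreatmentRule",
    "classify_ish",
    "trastuzumab_confusion",
    "clopper_pearson",
    "diagnostic_metrics",
    "tdxd_gold_standard",
    "lab_accuracy_profile",
]

AMPLIFIED_RATIO = 2.0


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        if self.total == 0:
            raise ValueError("empty confusion table")
        return (self.tn + self.tp) / self.total


@dataclass
class DiagnosticMetrics:
    """Point estimates with exact binomial CIs; undefined metrics are NaN."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    ci: dict[str, tuple[float, float]]
    alpha: float


def classify_ish(ratio: float) -> bool:
    """True (amplified) iff the HER2/CEP17 ratio is at least 2."""
    if ratio <= 0:
        raise ValueError("ISH ratio must be positive")
    return ratio >= AMPLIFIED_RATIO


def trastuzumab_confusion(
    consensus_scores: pd.DataFrame, ish_table: pd.DataFrame
) -> ConfusionCounts:
    """Confusion counts for over-expression calls against ISH.

    Gold positive: amplified (ratio >= 2).  IHC positive: a 3+ score, or a
    2+ score resolved positive by reflex ISH (the 2+ grey zone is, per
    guideline, adjudicated by the gene assay).  Non-evaluable cores must be
    excluded upstream; cores missing from either table are skipped.
    """
    ish = ish_table[ish_table.get("ish_evaluable", True) == True]  # noqa: E712
    merged = consensus_scores.merge(ish, on="core_id", how="inner")
    valid = set(SCORE_LEVELS)
    counts = ConfusionCounts()
    for row in merged.itertuples(index=False):
        score = float(row.rounded_score)
        if score not in valid:
            raise ValueError(f"invalid HER2 score {score}")
        amplified = classify_ish(row.ish_ratio)
        positive = score == 3.0 or (score == 2.0 and amplified)
        if positive and amplified:
            counts.tp += 1
        elif positive and not amplified:
            counts.fp += 1
        elif not positive and amplified:
            counts.fn += 1
        else:
            counts.tn += 1
    return counts


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles.

    The lower bound is 0 when ``k == 0`` and the upper bound 1 when
    ``k == n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def diagnostic_metrics(counts: ConfusionCounts, alpha: float = 0.05) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs.

    A metric whose denominator is zero is reported as NaN with a (NaN, NaN)
    interval rather than 0 or 1.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")

    def ratio(k: int, n: int) -> tuple[float, tuple[float, float]]:
        if n == 0:
            return float("nan"), (float("nan"), float("nan"))
        return k / n, clopper_pearson(k, n, alpha)

    sens, ci_sens = ratio(counts.tp, counts.tp + counts.fn)
    spec, ci_spec = ratio(counts.tn, counts.tn + counts.fp)
    ppv, ci_ppv = ratio(counts.tp, counts.tp + counts.fp)
    npv, ci_npv = ratio(counts.tn, counts.tn + counts.fn)
    acc, ci_acc = ratio(counts.tn + counts.tp, counts.total)
    return DiagnosticMetrics(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, accuracy=acc,
        ci={"sensitivity": ci_sens, "specificity": ci_spec, "ppv": ci_ppv,
            "npv": ci_npv, "accuracy": ci_acc},
        alpha=alpha,
    )


@dataclass(frozen=True)
class TreatmentRule:
    """Mapping from HER2 score (plus optional ISH status) to treat/no-treat.

    The default T-Dxd rule reconstructs the antibody-drug-conjugate
    eligibility used in the HER2-low trials: treat at scores 1+ or 2+
    (plus ultralow when that category is active); a 3+ score routes the
    patient to the anti-HER2-signalling pathway instead (no-treat for
    T-Dxd); a 2+ score resolved amplified by reflex ISH is likewise routed
    away when ISH data are supplied.  The mapping is total over the active
    score set, and alternative rules are plain data.
    """

    context: str = "t_dxd"
    include_ultralow: bool = True
    treat_scores: frozenset[float] = frozenset({0.5, 1.0, 2.0})
    exclude_amplified_2plus: bool = True

    def decide(self, score: float, amplified: bool | None = None) -> bool:
        """True = treat."""
        active = set(SCORE_LEVELS) if self.include_ultralow else set(cns.STANDARD_LEVELS)
        if score not in active:
            raise ValueError(f"score {score} outside the active set")
        treat = score in self.treat_scores
        if (treat and score == 2.0 and self.exclude_amplified_2plus
                and amplified is not None and amplified):
            treat = False
        return treat


def tdxd_gold_standard(
    score_matrix: pd.DataFrame,
    labs: pd.DataFrame,
    lod_criterion: LabCriterion,
    rule: TreatmentRule = TreatmentRule(),
    ish_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-core treat/no-treat decisions of the reference laboratory group.

    The reference decision is the rounded consensus of the labs selected by
    ``lod_criterion``, pushed through the treatment rule (with ISH status
    when a table is supplied).

    Columns: ``core_id, gold_score, gold_treat``.
    """
    ref_labs = cns.select_labs(labs, lod_criterion)
    cons = cns.consensus_scores(score_matrix, ref_labs, rule.include_ultralow)
    amp = _amplification_map(ish_table)
    cons["gold_treat"] = [
        rule.decide(s, amp.get(c)) for c, s in
        zip(cons["core_id"], cons["rounded_score"])
    ]
    return cons.rename(columns={"rounded_score": "gold_score"})[
        ["core_id", "gold_score", "gold_treat"]]


def _amplification_map(ish_table: pd.DataFrame | None) -> dict[str, bool]:
    if ish_table is None:
        return {}
    ev = ish_table[ish_table.get("ish_evaluable", True) == True]  # noqa: E712
    return {c: classify_ish(r) for c, r in
            zip(ev["core_id"], ev["ish_ratio"])}


def lab_accuracy_profile(
    score_matrix: pd.DataFrame,
    labs: pd.DataFrame,
    gold: pd.DataFrame,
    rule: TreatmentRule = TreatmentRule(),
    ish_table: pd.DataFrame | None = None,
    readout: str | None = None,
) -> pd.DataFrame:
    """Diagnostic accuracy of every laboratory against a gold decision table.

    Each lab's raw score per core is mapped through the treatment rule and
    compared with ``gold_treat``: agreement on treat is a TP, agreement on
    no-treat a TN, disagreement an FP or FN.  Labs with no scored cores are
    excluded.  Output is ordered by LOD.

    Columns: ``lab_id, lod, readout, tp, tn, fp, fn, accuracy``.
    """
    amp = _amplification_map(ish_table)
    gold_map = dict(zip(gold["core_id"], gold["gold_treat"]))
    pool = labs if readout is None else labs[labs["readout"] == readout]
    rows = []
    for lab in pool.itertuples(index=False):
        own = score_matrix[score_matrix["lab_id"] == lab.lab_id]
        own = own[own["core_id"].isin(gold_map)]
        if own.empty:
            continue
        score = own["score"].to_numpy(dtype=float)
        if not rule.include_ultralow:
            score = np.where(score == 0.5, 0.0, score)
        c = ConfusionCounts()
        for core_id, s in zip(own["core_id"], score):
            call = rule.decide(float(s), amp.get(core_id))
            truth = gold_map[core_id]
            if call and truth:
                c.tp += 1
            elif call and not truth:
                c.fp += 1
            elif not call and truth:
                c.fn += 1
            else:
                c.tn += 1
        rows.append({"lab_id": lab.lab_id, "lod": lab.true_lod,
                     "readout": lab.readout, "tp": c.tp, "tn": c.tn,
                     "fp": c.fp, "fn": c.fn, "accuracy": c.accuracy})
    return pd.DataFrame(rows).sort_values("lod").reset_index(drop=True)
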