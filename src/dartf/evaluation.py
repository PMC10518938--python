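"""Evaluation of predicted chemical-disease associations against a standard.

Per condition, the score vector is the condition's row of the triad matrix
and labels mark diseases curated as associated with that condition.
Condition-wise AUROC/AUPR are averaged unweighted over evaluable
conditions; "global" scores are computed on the merged vector that
concatenates every condition's (score, label) pairs, which weights the
actual score magnitudes across conditions. AUROC 1 is perfect ranking and
0.5 random; AUPR's random baseline is the positive prevalence.
"""

from __future__ import annotations

import logging
import os
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .triads import TriadMatrix

__all__ = [
    "StandardAssoc",
    "ConditionMetrics",
    "EvalReport",
    "auroc",
    "aupr",
    "evaluate",
    "compare_methods",
    "read_standard",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class StandardAssoc:
    """One curated positive chemical/pollutant-disease pair (CTD-style row)."""

    condition_id: str
    disease_id: str


@dataclass(frozen=True, slots=True)
class ConditionMetrics:
    auroc: float
    aupr: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class EvalReport:
    per_condition: dict[str, ConditionMetrics]
    mean_auroc: float
    mean_aupr: float
    global_auroc: float
    global_aupr: float
    excluded_conditions: tuple[str, ...] = ()


def _check_vectors(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    return s, y


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve with half-credit for score ties.

    Equals the Mann-Whitney statistic U / (n_pos * n_neg); ties are handled
    as a block (trapezoid over the tied segment) so the value is
    independent of within-tie ordering.
    """
    s, y = _check_vectors(scores, labels)
    if y.all() or not y.any():
        raise ValueError("AUROC requires at least one positive and one negative label")
    return float(roc_auc_score(y, s))


def aupr(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the precision-recall step curve (descending-score sweep,
    ties processed as one block). Constant scores give the positive
    prevalence, the random-classifier baseline."""
    s, y = _check_vectors(scores, labels)
    if not y.any():
        raise ValueError("AUPR requires at least one positive label")
    return float(average_precision_score(y, s))


def evaluate(matrix: TriadMatrix, standard: Iterable[StandardAssoc]) -> EvalReport:
    """Score a triad matrix against a Boolean chemical-disease standard.

    The disease universe per condition is the matrix's (shared) columns, so
    negatives are diseases scored but not curated for that condition.
    Conditions with zero positives or zero negatives among the columns are
    excluded from the per-condition map and the means (logged), but their
    cells stay in the merged global vector as all-negatives.
    """
    positives: dict[str, set[str]] = {}
    for assoc in standard:
        positives.setdefault(assoc.condition_id, set()).add(assoc.disease_id)
    if not set(matrix.conditions) & set(positives):
        raise ValueError("no condition of the matrix appears in the standard")

    per_condition: dict[str, ConditionMetrics] = {}
    excluded: list[str] = []
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    disease_arr = np.array(matrix.diseases)
    for i, cond in enumerate(matrix.conditions):
        pos = positives.get(cond, set())
        labels = np.isin(disease_arr, sorted(pos))
        scores = matrix.score[i]
        all_scores.append(scores)
        all_labels.append(labels)
        n_pos, n_neg = int(labels.sum()), int((~labels).sum())
        if n_pos == 0 or n_neg == 0:
            excluded.append(cond)
            logger.info(
                "condition %s excluded from per-condition metrics "
                "(n_pos=%d, n_neg=%d)", cond, n_pos, n_neg,
            )
            continue
        per_condition[cond] = ConditionMetrics(
            auroc=auroc(scores, labels),
            aupr=aupr(scores, labels),
            n_pos=n_pos,
            n_neg=n_neg,
        )
    if not per_condition:
        raise ValueError("no condition is evaluable (each needs >=1 positive and negative)")
    merged_scores = np.concatenate(all_scores)
    merged_labels = np.concatenate(all_labels)
    return EvalReport(
        per_condition=per_condition,
        mean_auroc=float(np.mean([m.auroc for m in per_condition.values()])),
        mean_aupr=float(np.mean([m.aupr for m in per_condition.values()])),
        global_auroc=auroc(merged_scores, merged_labels),
        global_aupr=aupr(merged_scores, merged_labels),
        excluded_conditions=tuple(excluded),
    )


def compare_methods(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_comparisons: int = 1,
) -> tuple[float, float]:
    """Unpaired two-tailed Wilcoxon rank-sum comparison of two metric
    distributions with Bonferroni adjustment.

    Exact enumeration for small tie-free groups (both sizes <= 20), normal
    approximation with tie correction otherwise. Returns
    (U statistic, min(1, p * n_comparisons)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be a positive integer")
    tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (tie_free and max(a.size, b.size) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue * n_comparisons))


def read_standard(path: str | os.PathLike) -> list[StandardAssoc]:
    """TSV with header condition_id, disease_id; duplicate pairs dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"condition_id", "disease_id"} - set(df.columns)
    if missing:
        raise ValueError(f"standard table {path} lacks columns: {sorted(missing)}")
    df = df.drop_duplicates(subset=["condition_id", "disease_id"])
    return [StandardAssoc(r.condition_id, r.disease_id) for r in df.itertuples(index=False)]


def write_report(report: EvalReport, path: str | os.PathLike) -> str:
    """Per-condition rows followed by summary rows, 6-significant-digit TSV."""
    rows = [
        (cond, f"{m.auroc:.6g}", f"{m.aupr:.6g}", m.n_pos, m.n_neg)
        for cond, m in report.per_condition.items()
    ]
    rows += [
        ("mean", f"{report.mean_auroc:.6g}", f"{report.mean_aupr:.6g}", "", ""),
        ("global", f"{report.global_auroc:.6g}", f"{report.global_aupr:.6g}", "", ""),
    ]
    pd.DataFrame(rows, columns=["condition_id", "auroc", "aupr", "n_pos", "n_neg"]).to_csv(
        path, sep="\t", index=False
    )
    return os.fspath(path)
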