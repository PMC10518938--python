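"""Chemical-TF-disease triadic association scoring.

Per-condition collapsed TF enrichment is joined with a TF-disease table:
for each (condition, disease) cell the score is the maximum enrichment
score over TFs linked to that disease, and the mediator is the argmax TF.
Cells with no linking TF score 0 (kept, so every condition has a complete
score vector for evaluation). Antigen/gene symbols are matched exactly
after uppercasing — no ortholog mapping.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult

__all__ = [
    "TFDiseaseAssoc",
    "TriadMatrix",
    "build_triads",
    "read_tf_disease_assoc",
    "write_triad_matrix",
]


@dataclass(frozen=True, slots=True)
class TFDiseaseAssoc:
    """One curated TF-disease link (DisGeNET-style row)."""

    antigen: str
    disease_id: str
    source: str = ""


@dataclass(frozen=True)
class TriadMatrix:
    """Condition x disease enrichment-score matrix with the mediating TF per cell.

    ``score[i, j] == 0`` means no TF links condition i to disease j and
    ``mediator[i, j]`` is the empty string.
    """

    conditions: tuple[str, ...]
    diseases: tuple[str, ...]
    score: np.ndarray
    mediator: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m, n = len(self.conditions), len(self.diseases)
        if self.score.shape != (m, n) or self.mediator.shape != (m, n):
            raise ValueError(
                f"matrix shapes {self.score.shape}/{self.mediator.shape} "
                f"inconsistent with {m} conditions x {n} diseases"
            )

    def row(self, condition_id: str) -> np.ndarray:
        return self.score[self.conditions.index(condition_id)]


def build_triads(
    per_condition_results: Mapping[str, Sequence[EnrichmentResult]],
    assoc: Iterable[TFDiseaseAssoc],
    standard_diseases: Iterable[str] = (),
) -> TriadMatrix:
    """Join collapsed per-condition enrichment with TF-disease links.

    Disease columns are the associated diseases reachable from at least one
    condition's TF vocabulary, plus any diseases named in a supplied
    evaluation standard (so evaluation labels stay complete); both are
    sorted for determinism. Ties among TFs at the maximal score resolve to
    the lexicographically smallest TF symbol.
    """
    assoc = list(assoc)
    if not assoc:
        raise ValueError("TF-disease association table is empty")
    if not per_condition_results:
        raise ValueError("no per-condition enrichment results supplied")

    # disease -> set of linked TFs, uppercased; duplicate rows collapse here
    disease_tfs: dict[str, set[str]] = {}
    for link in assoc:
        disease_tfs.setdefault(link.disease_id, set()).add(link.antigen.upper())

    # condition -> TF -> max enrichment score (input is collapsed, but a max
    # here keeps the join safe if multiple rows per antigen slip through)
    cond_scores: dict[str, dict[str, float]] = {}
    for cond, results in per_condition_results.items():
        scores: dict[str, float] = {}
        for res in results:
            tf = res.antigen.upper()
            if res.enrichment_score > scores.get(tf, -1.0):
                scores[tf] = res.enrichment_score
        cond_scores[cond] = scores

    all_tfs_seen = set().union(*(set(s) for s in cond_scores.values()))
    reachable = {
        dis for dis, tfs in disease_tfs.items() if tfs & all_tfs_seen
    }
    diseases = tuple(sorted(reachable | set(standard_diseases)))
    conditions = tuple(cond_scores)

    score = np.zeros((len(conditions), len(diseases)))
    mediator = np.full((len(conditions), len(diseases)), "", dtype=object)
    for i, cond in enumerate(conditions):
        scores = cond_scores[cond]
        for j, dis in enumerate(diseases):
            best_tf, best = "", 0.0
            for tf in sorted(disease_tfs.get(dis, ())):
                s = scores.get(tf)
                if s is not None and s > best:
                    best_tf, best = tf, s
            score[i, j] = best
            mediator[i, j] = best_tf
    return TriadMatrix(conditions, diseases, score, mediator)


def read_tf_disease_assoc(path: str | os.PathLike) -> list[TFDiseaseAssoc]:
    """TSV with header antigen, disease_id[, source]; duplicate
    (antigen, disease_id) pairs are dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"antigen", "disease_id"} - set(df.columns)
    if missing:
        raise ValueError(f"association table {path} lacks columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = ""
    df = df.drop_duplicates(subset=["antigen", "disease_id"])
    return [
        TFDiseaseAssoc(row.antigen, row.disease_id, row.source)
        for row in df.itertuples(index=False)
    ]


def write_triad_matrix(
    matrix: TriadMatrix, long_path: str | os.PathLike, wide_path: str | os.PathLike
) -> tuple[str, str]:
    """Long TSV (condition_id, disease_id, score, mediator) and wide m x n TSV."""
    rows = [
        (cond, dis, matrix.score[i, j], matrix.mediator[i, j])
        for i, cond in enumerate(matrix.conditions)
        for j, dis in enumerate(matrix.diseases)
    ]
    pd.DataFrame(rows, columns=["condition_id", "disease_id", "score", "mediator"]).to_csv(
        long_path, sep="\t", index=False, float_format="%.6g"
    )
    wide = pd.DataFrame(matrix.score, index=matrix.conditions, columns=matrix.diseases)
    wide.index.name = "condition_id"
    wide.to_csv(wide_path, sep="\t", float_format="%.6g")
    return os.fspath(long_path), os.fspath(wide_path)
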