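"""ChIP-seq peak-overlap TF enrichment (ChIPEA-style).

For one condition's opened and closed DARs and a library of peak-set
experiments, each experiment gets a 2x2 table

    a = opened DARs overlapping its peaks     b = opened DARs not overlapping
    c = closed DARs overlapping its peaks     d = closed DARs not overlapping

tested with a two-tailed Fisher's exact test, Benjamini-Hochberg adjusted
across the whole library; the enrichment score is -log10(Q), capped, and
log2 fold enrichment is the (smoothed) ratio of the opened-DAR overlap rate
to the closed-DAR overlap rate. Multiple experiments for one antigen are
collapsed to the highest-scoring one. DEG mode reuses the same operations
with up-/down-regulated TSS windows substituted for opened/closed DARs.
"""

from __future__ import annotations

import dataclasses
import math
import os
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dars import DARSet
from .intervals import OverlapIndex, PeakSet

__all__ = [
    "EnrichmentResult",
    "fisher_exact_two_tailed",
    "bh_adjust",
    "enrich",
    "collapse_by_antigen",
    "filter_by_cell_type_class",
    "results_to_frame",
    "write_results",
]

DEFAULT_SCORE_CAP = 500.0


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """One experiment's 2x2 counts and enrichment statistics."""

    experiment_id: str
    antigen: str
    cell_type_class: str
    a: int
    b: int
    c: int
    d: int
    p_value: float
    q_value: float
    enrichment_score: float
    log2_fold_enrichment: float


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher probability for the 2x2 table [[a, b], [c, d]].

    With margins fixed, sums the hypergeometric probabilities of every table
    whose point probability is <= that of the observed table (within a small
    relative tolerance for ties). A degenerate margin carries no information
    and yields p = 1 with a warning.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError(f"counts must be non-negative, got {counts}")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        warnings.warn(
            f"degenerate 2x2 margin in table {counts}: p = 1 (no information)",
            stacklevel=2,
        )
        return 1.0
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return float(min(p, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, aligned with input order.

    q_(i) = min over j >= i of min(1, p_(j) * m / j) on the sorted p-values,
    mapped back to the original positions.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _log2_fold_enrichment(a: int, b: int, c: int, d: int, cap: float) -> float:
    """Signed log2 of (opened overlap rate / closed overlap rate), with a
    Haldane-style +0.5 smoothing on the rates so the value stays finite when
    either overlap count is zero; capped to +/- cap."""
    rate_open = (a + 0.5) / (a + b + 0.5)
    rate_closed = (c + 0.5) / (c + d + 0.5)
    lfe = math.log2(rate_open / rate_closed)
    return max(-cap, min(cap, lfe))


def enrich(
    dars: DARSet,
    library: Sequence[PeakSet],
    score_cap: float = DEFAULT_SCORE_CAP,
) -> list[EnrichmentResult]:
    """Score every library experiment for differential overlap between the
    condition's opened and closed DARs.

    BH adjustment spans all experiments of this call (one condition against
    one library — the family a single enrichment submission would form).
    enrichment_score = min(-log10 q, score_cap).
    """
    if not dars.opened or not dars.closed:
        raise ValueError(
            f"condition {dars.condition_id!r} has an empty opened or closed set "
            f"({len(dars.opened)} opened, {len(dars.closed)} closed) and cannot be tested"
        )
    if not library:
        raise ValueError("peak library is empty")
    if dars.genome:
        mismatched = sorted(
            {ps.genome for ps in library if ps.genome and ps.genome != dars.genome}
        )
        if mismatched:
            raise ValueError(
                f"library genome builds {mismatched} do not match DARs on {dars.genome!r}"
            )
    n_open, n_closed = len(dars.opened), len(dars.closed)
    tables: list[tuple[int, int, int, int]] = []
    p_values: list[float] = []
    for ps in library:
        idx = OverlapIndex(ps)
        a = idx.count_overlapping(dars.opened)
        c = idx.count_overlapping(dars.closed)
        b, d = n_open - a, n_closed - c
        tables.append((a, b, c, d))
        if a == 0 and c == 0:
            # no overlap anywhere: no signal, skip the degenerate-margin warning
            p_values.append(1.0)
        else:
            p_values.append(fisher_exact_two_tailed(a, b, c, d))
    q_values = bh_adjust(p_values)
    results = []
    for ps, (a, b, c, d), p, q in zip(library, tables, p_values, q_values):
        score = min(-math.log10(q), score_cap) if q > 0 else score_cap
        results.append(
            EnrichmentResult(
                experiment_id=ps.experiment_id,
                antigen=ps.antigen,
                cell_type_class=ps.cell_type_class,
                a=a, b=b, c=c, d=d,
                p_value=float(p),
                q_value=float(q),
                enrichment_score=float(score),
                log2_fold_enrichment=0.0 if (a == 0 and c == 0)
                else _log2_fold_enrichment(a, b, c, d, score_cap),
            )
        )
    return results


def collapse_by_antigen(results: Iterable[EnrichmentResult]) -> list[EnrichmentResult]:
    """Keep, per antigen, the single highest-scoring experiment.

    Ties on enrichment_score break toward larger |log2_fold_enrichment|,
    then the lexicographically smallest experiment_id, so the output is
    deterministic. Results are returned sorted by antigen.
    """
    best: dict[str, EnrichmentResult] = {}
    for res in results:
        key = (
            res.enrichment_score,
            abs(res.log2_fold_enrichment),
        )
        inc = best.get(res.antigen)
        if inc is None:
            best[res.antigen] = res
            continue
        inc_key = (inc.enrichment_score, abs(inc.log2_fold_enrichment))
        if key > inc_key or (key == inc_key and res.experiment_id < inc.experiment_id):
            best[res.antigen] = res
    return [best[ag] for ag in sorted(best)]


def filter_by_cell_type_class(
    library: Iterable[PeakSet], cell_type_class: str | None
) -> list[PeakSet]:
    """Restrict a library to one cell-type class; None means no filtering."""
    if cell_type_class is None:
        return list(library)
    return [ps for ps in library if ps.cell_type_class == cell_type_class]


_COLUMNS = [
    "experiment_id", "antigen", "cell_type_class",
    "a", "b", "c", "d",
    "p_value", "q_value", "enrichment_score", "log2_fold_enrichment",
]


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results], columns=_COLUMNS)


def write_results(results: Iterable[EnrichmentResult], path: str | os.PathLike) -> str:
    """TSV with fixed column order and 6-significant-digit floats."""
    results_to_frame(results).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
    return os.fspath(path)
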