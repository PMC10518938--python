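"""Differentially accessible region (DAR) calling.

A condition's accessible chromatin is the bp-level genomic intersection of
its replicate peak sets. A DAR is then a whole accessible region of one
group (exposed or control) with zero overlap against every accessible
region of the other group: exposure-specific regions are "opened" DARs,
control-specific regions are "closed" DARs. For gene-list (DEG) mode,
genes are represented as windows of +/- `flank` bp around the TSS.
"""

from __future__ import annotations

import logging
import os
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .intervals import GenomicInterval, OverlapIndex, PeakSet, write_bed

__all__ = [
    "DARSet",
    "GeneAnnotation",
    "intersect_replicates",
    "detect_dars",
    "genes_to_windows",
    "read_gene_annotation",
    "read_chrom_sizes",
    "write_darset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DARSet:
    """Opened and closed DARs for one perturbation condition."""

    condition_id: str
    genome: str
    opened: tuple[GenomicInterval, ...]
    closed: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "opened", tuple(self.opened))
        object.__setattr__(self, "closed", tuple(self.closed))


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """TSS location of one gene, 0-based; strand determines which gene end
    the annotation's TSS coordinate refers to."""

    symbol: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def _merge_union(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union coverage of intervals as sorted, disjoint, score-less intervals."""
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def _intersect_two(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """bp-level intersection of two sorted disjoint interval lists (sweep)."""
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        x, y = a[i], b[j]
        if x.chrom != y.chrom:
            if x.chrom < y.chrom:
                i += 1
            else:
                j += 1
            continue
        lo, hi = max(x.start, y.start), min(x.end, y.end)
        if lo < hi:
            out.append(GenomicInterval(x.chrom, lo, hi))
        # advance whichever ends first
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return out


def intersect_replicates(replicates: Sequence[PeakSet]) -> tuple[GenomicInterval, ...]:
    """Genomic regions covered by >=1 peak in EVERY replicate.

    Returns maximal sub-intervals (bp-level intersection, as BEDtools
    intersection of the replicates' union coverage), sorted by
    (chrom, start) and mutually non-overlapping.
    """
    if not replicates:
        raise ValueError("at least one replicate peak set is required")
    genomes = {rep.genome for rep in replicates}
    if len(genomes) > 1:
        raise ValueError(f"replicates span multiple genome builds: {sorted(genomes)}")
    common = _merge_union(replicates[0])
    for rep in replicates[1:]:
        common = _intersect_two(common, _merge_union(rep))
    return tuple(common)


def detect_dars(
    exposed_common: Iterable[GenomicInterval],
    control_common: Iterable[GenomicInterval],
    condition_id: str,
    genome: str = "",
) -> DARSet:
    """Call opened/closed DARs as group-exclusive accessible regions.

    opened = exposed regions with zero bp overlap against every control
    region; closed = the converse. Regions are kept whole — a region either
    survives the non-overlap filter intact or is discarded. Empty outputs
    are recorded, not an error.
    """
    exposed = tuple(exposed_common)
    control = tuple(control_common)
    control_idx = OverlapIndex(control)
    exposed_idx = OverlapIndex(exposed)
    opened = tuple(iv for iv in exposed if not control_idx.overlaps(iv))
    closed = tuple(iv for iv in control if not exposed_idx.overlaps(iv))
    logger.info(
        "condition %s: %d exposed-common, %d control-common -> %d opened, %d closed DARs",
        condition_id, len(exposed), len(control), len(opened), len(closed),
    )
    return DARSet(condition_id=condition_id, genome=genome, opened=opened, closed=closed)


def genes_to_windows(
    symbols: Iterable[str],
    annotation: Iterable[GeneAnnotation] | Mapping[str, GeneAnnotation],
    flank: int = 5000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[tuple[GenomicInterval, ...], tuple[str, ...]]:
    """Convert gene symbols to TSS windows ``[tss - flank, tss + flank)``.

    Windows are clamped to ``[0, chrom length)`` when sizes are provided
    and duplicates are collapsed. Returns ``(windows, skipped_symbols)``;
    raises if no symbol resolves, since an empty query would poison the
    downstream enrichment.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    if isinstance(annotation, Mapping):
        by_symbol = dict(annotation)
    else:
        by_symbol = {ann.symbol: ann for ann in annotation}
    windows: list[GenomicInterval] = []
    seen: set[tuple[str, int, int]] = set()
    skipped: list[str] = []
    for symbol in symbols:
        ann = by_symbol.get(symbol)
        if ann is None:
            skipped.append(symbol)
            continue
        start = max(0, ann.tss - flank)
        end = ann.tss + flank
        if chrom_sizes is not None and ann.chrom in chrom_sizes:
            end = min(end, chrom_sizes[ann.chrom])
        key = (ann.chrom, start, end)
        if key not in seen:
            seen.add(key)
            windows.append(GenomicInterval(*key))
    if not windows:
        raise ValueError("no input gene symbol resolved against the annotation")
    if skipped:
        logger.warning("%d gene symbols not found in annotation: %s",
                       len(skipped), ", ".join(skipped[:10]))
    return tuple(windows), tuple(skipped)


def read_gene_annotation(path: str | os.PathLike) -> dict[str, GeneAnnotation]:
    """TSV with header symbol, chrom, tss, strand -> symbol-indexed mapping."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str, "strand": str})
    missing = {"symbol", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation {path} lacks columns: {sorted(missing)}")
    return {
        row.symbol: GeneAnnotation(row.symbol, row.chrom, int(row.tss), row.strand)
        for row in df.itertuples(index=False)
    }


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Two-column headerless TSV (chrom, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_darset(dars: DARSet, outdir: str | os.PathLike) -> tuple[str, str]:
    """Serialize as <condition>.opened.bed / <condition>.closed.bed (BED3)."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for label, intervals in (("opened", dars.opened), ("closed", dars.closed)):
        ps = PeakSet(
            experiment_id=f"{dars.condition_id}.{label}",
            antigen="DAR",
            cell_type_class="",
            genome=dars.genome,
            intervals=intervals,
        )
        paths.append(write_bed(ps, os.path.join(outdir, f"{dars.condition_id}.{label}.bed")))
    return paths[0], paths[1]
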