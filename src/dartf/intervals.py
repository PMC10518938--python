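"""Genomic interval data model, BED I/O and overlap queries.

Coordinates are BED-native throughout: 0-based, half-open ``[start, end)``.
``[10, 20)`` and ``[20, 30)`` are adjacent, not overlapping. Chromosome names
are matched as exact strings ("chr1" != "1"); :func:`normalize_chr_prefix`
can be applied up front when mixing dialects.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "BedParseError",
    "OverlapIndex",
    "read_bed",
    "write_bed",
    "filter_by_score",
    "count_overlapping_queries",
    "normalize_chr_prefix",
    "read_library_manifest",
]

# BED column-5 score is conventionally clamped to this range on output.
_BED_SCORE_MAX = 1000


class BedParseError(ValueError):
    """Raised when a BED line cannot be interpreted; carries the line number."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """One half-open region ``[start, end)`` on a named chromosome.

    ``score`` follows the BED column-5 convention of peak callers,
    ``int(-10 * log10 Q)``; ``None`` for score-less (BED3) intervals.
    """

    chrom: str
    start: int
    end: int
    score: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.score is not None and self.score < 0:
            raise ValueError(f"score must be non-negative, got {self.score}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp overlap under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PeakSet:
    """The intervals of one peak-called experiment plus its metadata.

    ``antigen`` is the ChIP'd factor for TF ChIP-seq, or an assay label
    (e.g. "ATAC") for accessibility data; ``cell_type_class`` mirrors the
    ChIP-Atlas cell-type grouping.
    """

    experiment_id: str
    antigen: str
    cell_type_class: str
    genome: str
    intervals: tuple[GenomicInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def _parse_bed_line(line: str, lineno: int) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinate: {exc}") from None
    score: int | None = None
    if len(fields) >= 5 and fields[4] not in ("", "."):
        try:
            score = int(fields[4])
        except ValueError:
            raise BedParseError(f"line {lineno}: non-integer score {fields[4]!r}") from None
    try:
        return GenomicInterval(chrom, start, end, score)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from None


def read_bed(
    path: str | os.PathLike,
    genome: str = "",
    experiment_id: str = "",
    antigen: str = "",
    cell_type_class: str = "",
) -> PeakSet:
    """Read a BED3/BED5 file into a :class:`PeakSet`, preserving file order.

    Track/browser lines and ``#`` comments are skipped; column 5, when
    present, is stored as the interval score; extra columns are ignored.
    An empty file yields an empty PeakSet.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_bed_line(line, lineno))
    return PeakSet(
        experiment_id=experiment_id or os.path.basename(os.fspath(path)),
        antigen=antigen,
        cell_type_class=cell_type_class,
        genome=genome,
        intervals=tuple(intervals),
    )


def write_bed(peaks: PeakSet, path: str | os.PathLike) -> str:
    """Write a PeakSet as BED: 5 columns when every interval carries a score
    (names autogenerated as ``<experiment_id>.<index>``, scores clamped to
    [0, 1000] per the BED convention), 3 columns otherwise.
    """
    scored = len(peaks) > 0 and all(iv.score is not None for iv in peaks)
    with open(path, "w") as fh:
        for i, iv in enumerate(peaks):
            if scored:
                clamped = min(iv.score, _BED_SCORE_MAX)  # type: ignore[arg-type]
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.experiment_id}.{i}\t{clamped}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    return os.fspath(path)


def filter_by_score(peaks: PeakSet, min_score: int) -> PeakSet:
    """Retain intervals with ``score >= min_score``.

    ``min_score=100`` corresponds to MACS2 Q <= 1e-10 under the
    ``int(-10 * log10 Q)`` score convention.
    """
    if any(iv.score is None for iv in peaks):
        raise ValueError(
            f"peak set {peaks.experiment_id!r} has intervals without scores; "
            "3-column BED sets must be used unfiltered"
        )
    kept = tuple(iv for iv in peaks if iv.score >= min_score)  # type: ignore[operator]
    return replace(peaks, intervals=kept)


class OverlapIndex:
    """Per-chromosome interval-tree index over a collection of intervals.

    Built once per peak set, then queried per interval; half-open
    semantics match the rest of the package.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        self._trees = trees

    def overlaps(self, query: GenomicInterval) -> bool:
        tree = self._trees.get(query.chrom)
        return bool(tree is not None and tree.overlaps(query.start, query.end))

    def count_overlapping(self, queries: Iterable[GenomicInterval]) -> int:
        """Number of DISTINCT queries overlapping >=1 indexed interval by >=1 bp."""
        return sum(1 for q in queries if self.overlaps(q))


def count_overlapping_queries(
    queries: Iterable[GenomicInterval], peaks: PeakSet | Iterable[GenomicInterval]
) -> int:
    """Count query intervals that overlap at least one peak by >=1 bp.

    Each query is counted at most once however many peaks it touches; this
    binary per-query semantics is what keeps the downstream 2x2 contingency
    margins fixed. Empty inputs give 0.
    """
    return OverlapIndex(peaks).count_overlapping(queries)


def normalize_chr_prefix(intervals: Iterable[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Map bare chromosome names ("1", "X") to UCSC-style ("chr1", "chrX")."""
    return tuple(
        iv if iv.chrom.startswith("chr") else replace(iv, chrom=f"chr{iv.chrom}")
        for iv in intervals
    )


def read_library_manifest(path: str | os.PathLike) -> list[PeakSet]:
    """Load a peak library from a manifest TSV.

    Header columns: experiment_id, antigen, cell_type_class, genome, path.
    BED paths are resolved relative to the manifest's directory; experiment
    IDs must be unique within the library.
    """
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    required = {"experiment_id", "antigen", "cell_type_class", "genome", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    if manifest["experiment_id"].duplicated().any():
        dupes = manifest.loc[manifest["experiment_id"].duplicated(), "experiment_id"]
        raise ValueError(f"duplicate experiment_id in manifest: {sorted(set(dupes))}")
    base = os.path.dirname(os.path.abspath(os.fspath(path)))
    library = []
    for row in manifest.itertuples(index=False):
        bed_path = row.path
        if not os.path.isabs(bed_path):
            bed_path = os.path.join(base, bed_path)
        library.append(
            read_bed(
                bed_path,
                genome=row.genome,
                experiment_id=row.experiment_id,
                antigen=row.antigen,
                cell_type_class=row.cell_type_class,
            )
        )
    return library
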