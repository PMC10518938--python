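"""Deterministic synthetic data: toy genomes, ATAC replicate peak sets with
planted opened/closed loci, ChIP-seq-style peak libraries with planted TF
enrichment, and consistent TF-disease / chemical-disease tables.

The generator emulates, at desk scale, the shape of the real inputs: peak
BEDs per replicate for exposed and control groups, a peak library annotated
with antigen and cell-type class, a curated TF-disease table, and a Boolean
chemical-disease standard. Planted TFs cover opened loci with probability
``p_fg`` and closed loci with ``p_bg``; non-planted TFs cover both at
``p_bg``. Every output is a pure function of the :class:`SimConfig` (one
pseudo-random stream per stage, derived from the master seed by fixed
offsets, so e.g. changing ``n_tfs`` does not perturb DAR placement).
"""

from __future__ import annotations

import json
import os
from collections.abc import Sequence
from dataclasses import dataclass, field, asdict

import numpy as np

from .intervals import GenomicInterval, PeakSet, write_bed
from .triads import TFDiseaseAssoc
from .evaluation import StandardAssoc

__all__ = [
    "SimConfig",
    "ConditionTruth",
    "simulate_condition",
    "simulate_library",
    "simulate_associations",
    "write_dataset",
]

# fixed stream offsets; one independent RNG per generator stage
_STREAM_LOCI = 0
_STREAM_REPLICATES = 1
_STREAM_LIBRARY = 2
_STREAM_ASSOC = 3

_MIN_PEAK_SCORE = 100  # at/above the default peak-score filter threshold
_MAX_PEAK_SCORE = 1000


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic perturbation experiment.

    Defaults are the planted-recovery benchmark conditions: 200 DARs per
    side, a 10-TF library with 2 planted TFs, foreground/background overlap
    probabilities 0.9/0.1.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_dars_opened: int = 200
    n_dars_closed: int = 200
    n_background: int = 200
    dar_width: int = 400
    jitter: int = 50
    n_replicates: int = 2
    n_tfs: int = 10
    experiments_per_tf: int = 2
    peak_width: int = 400
    n_decoy_peaks: int = 200
    p_fg: float = 0.9
    p_bg: float = 0.1
    planted_tfs: tuple[str, ...] = ("TF01", "TF02")
    n_diseases: int = 20
    n_noise_assoc: int = 30
    condition_id: str = "synthetic-condition"
    genome: str = "toy1"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bg <= self.p_fg <= 1.0):
            raise ValueError(
                f"need 0 <= p_bg <= p_fg <= 1, got p_bg={self.p_bg}, p_fg={self.p_fg}"
            )
        for name in ("n_chroms", "chrom_length", "n_dars_opened", "n_dars_closed",
                     "dar_width", "n_replicates", "n_tfs", "experiments_per_tf",
                     "peak_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.jitter < 0 or self.n_background < 0 or self.n_decoy_peaks < 0:
            raise ValueError("jitter, n_background and n_decoy_peaks must be >= 0")
        if self.dar_width <= 2 * self.jitter:
            raise ValueError("dar_width must exceed 2 * jitter or replicate "
                             "intersection may vanish")
        if self.n_diseases < self.n_tfs:
            raise ValueError("n_diseases must be >= n_tfs (one dedicated disease per TF)")
        unknown = set(self.planted_tfs) - set(self.tf_labels)
        if unknown:
            raise ValueError(f"planted_tfs not in TF label set: {sorted(unknown)}")
        if len(self.planted_tfs) >= self.n_tfs:
            raise ValueError("at least one TF must remain non-planted (negative control)")
        object.__setattr__(self, "planted_tfs", tuple(self.planted_tfs))

    @property
    def tf_labels(self) -> tuple[str, ...]:
        return tuple(f"TF{i + 1:02d}" for i in range(self.n_tfs))

    @property
    def disease_labels(self) -> tuple[str, ...]:
        return tuple(f"D{i + 1:03d}" for i in range(self.n_diseases))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class ConditionTruth:
    """Planted ground truth for one simulated condition."""

    condition_id: str
    genome: str
    opened_loci: tuple[GenomicInterval, ...]
    closed_loci: tuple[GenomicInterval, ...]
    background_loci: tuple[GenomicInterval, ...]
    planted_tfs: tuple[str, ...]

    def to_json(self, path: str | os.PathLike) -> str:
        def ser(ivs):
            return [[iv.chrom, iv.start, iv.end] for iv in ivs]
        payload = {
            "condition_id": self.condition_id,
            "genome": self.genome,
            "opened_loci": ser(self.opened_loci),
            "closed_loci": ser(self.closed_loci),
            "background_loci": ser(self.background_loci),
            "planted_tfs": list(self.planted_tfs),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return os.fspath(path)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "ConditionTruth":
        with open(path) as fh:
            d = json.load(fh)
        des = lambda rows: tuple(GenomicInterval(c, s, e) for c, s, e in rows)
        return cls(
            condition_id=d["condition_id"],
            genome=d["genome"],
            opened_loci=des(d["opened_loci"]),
            closed_loci=des(d["closed_loci"]),
            background_loci=des(d["background_loci"]),
            planted_tfs=tuple(d["planted_tfs"]),
        )


def _place_loci(config: SimConfig, rng: np.random.Generator) -> list[GenomicInterval]:
    """Place all truth loci uniformly, mutually separated by more than
    2 * jitter bp so per-replicate jitter can never merge two loci or cross
    the group non-overlap criterion."""
    n_total = config.n_dars_opened + config.n_dars_closed + config.n_background
    gap = 2 * config.jitter + 10
    per_chrom = np.full(config.n_chroms, n_total // config.n_chroms)
    per_chrom[: n_total % config.n_chroms] += 1
    loci: list[GenomicInterval] = []
    for c, n_c in enumerate(per_chrom):
        n_c = int(n_c)
        if n_c == 0:
            continue
        chrom = f"chr{c + 1}"
        needed = n_c * (config.dar_width + gap)
        if needed > config.chrom_length:
            raise ValueError(
                f"cannot place {n_c} loci of width {config.dar_width} with "
                f"separation {gap} on a {config.chrom_length} bp chromosome; "
                "use a larger genome or fewer/narrower loci"
            )
        slack = config.chrom_length - needed
        offsets = np.sort(rng.integers(0, slack + 1, size=n_c))
        for i, off in enumerate(offsets):
            start = int(off + i * (config.dar_width + gap))
            loci.append(GenomicInterval(chrom, start, start + config.dar_width))
    return loci


def simulate_condition(
    config: SimConfig,
) -> tuple[list[PeakSet], list[PeakSet], ConditionTruth]:
    """Generate exposed and control ATAC-style replicate peak sets.

    Exposed replicates carry peaks over the opened-truth loci plus a shared
    accessible background; control replicates carry peaks over the
    closed-truth loci plus the same background. Per-replicate coordinate
    jitter (each edge shifted by up to ``jitter`` bp) never crosses the
    group non-overlap criterion by construction.
    """
    loci_rng = config.rng(_STREAM_LOCI)
    loci = _place_loci(config, loci_rng)
    order = loci_rng.permutation(len(loci))
    n_o, n_c = config.n_dars_opened, config.n_dars_closed
    opened = tuple(loci[i] for i in sorted(order[:n_o]))
    closed = tuple(loci[i] for i in sorted(order[n_o : n_o + n_c]))
    background = tuple(loci[i] for i in sorted(order[n_o + n_c :]))
    truth = ConditionTruth(
        condition_id=config.condition_id,
        genome=config.genome,
        opened_loci=opened,
        closed_loci=closed,
        background_loci=background,
        planted_tfs=config.planted_tfs,
    )

    rep_rng = config.rng(_STREAM_REPLICATES)

    def make_replicates(group: str, group_loci: Sequence[GenomicInterval]) -> list[PeakSet]:
        reps = []
        for r in range(config.n_replicates):
            intervals = []
            for locus in group_loci:
                if config.jitter:
                    d1 = int(rep_rng.integers(-config.jitter, config.jitter + 1))
                    d2 = int(rep_rng.integers(-config.jitter, config.jitter + 1))
                else:
                    d1 = d2 = 0
                score = int(rep_rng.integers(_MIN_PEAK_SCORE, _MAX_PEAK_SCORE + 1))
                intervals.append(
                    GenomicInterval(
                        locus.chrom, max(0, locus.start + d1), locus.end + d2, score
                    )
                )
            intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
            reps.append(
                PeakSet(
                    experiment_id=f"{config.condition_id}.{group}.rep{r + 1}",
                    antigen="ATAC",
                    cell_type_class="synthetic",
                    genome=config.genome,
                    intervals=tuple(intervals),
                )
            )
        return reps

    exposed = make_replicates("exposed", opened + background)
    control = make_replicates("control", closed + background)
    return exposed, control, truth


def simulate_library(config: SimConfig, truth: ConditionTruth) -> list[PeakSet]:
    """Generate a ChIP-seq-style peak library with planted enrichment.

    Each of the ``n_tfs x experiments_per_tf`` experiments covers each
    opened-truth locus with probability ``p_fg`` if its TF is planted, else
    ``p_bg``, and each closed-truth locus with probability ``p_bg``;
    uniform decoy peaks are added and all scores are drawn at or above the
    default peak-score filter threshold.
    """
    rng = config.rng(_STREAM_LIBRARY)
    planted = set(truth.planted_tfs)
    library: list[PeakSet] = []

    def peak_over(locus: GenomicInterval) -> GenomicInterval:
        center = (locus.start + locus.end) // 2
        start = max(0, center - config.peak_width // 2)
        score = int(rng.integers(_MIN_PEAK_SCORE, _MAX_PEAK_SCORE + 1))
        return GenomicInterval(locus.chrom, start, start + config.peak_width, score)

    for tf in config.tf_labels:
        p_open = config.p_fg if tf in planted else config.p_bg
        for e in range(config.experiments_per_tf):
            intervals: list[GenomicInterval] = []
            for locus in truth.opened_loci:
                if rng.random() < p_open:
                    intervals.append(peak_over(locus))
            for locus in truth.closed_loci:
                if rng.random() < config.p_bg:
                    intervals.append(peak_over(locus))
            for _ in range(config.n_decoy_peaks):
                chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
                start = int(rng.integers(0, config.chrom_length - config.peak_width))
                score = int(rng.integers(_MIN_PEAK_SCORE, _MAX_PEAK_SCORE + 1))
                intervals.append(
                    GenomicInterval(chrom, start, start + config.peak_width, score)
                )
            intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
            library.append(
                PeakSet(
                    experiment_id=f"{tf}.exp{e + 1:02d}",
                    antigen=tf,
                    cell_type_class="synthetic",
                    genome=config.genome,
                    intervals=tuple(intervals),
                )
            )
    return library


def simulate_associations(
    config: SimConfig, truth: ConditionTruth
) -> tuple[list[TFDiseaseAssoc], list[StandardAssoc]]:
    """Generate consistent TF-disease links and a chemical-disease standard.

    Every TF gets a base link to its own dedicated disease: planted TFs'
    diseases become the condition's standard positives, and non-planted
    TFs' diseases guarantee negative columns (so every condition has >=1
    positive and >=1 negative). ``n_noise_assoc`` extra links are drawn
    among non-planted TFs and random diseases, leaving the planted ground
    truth unambiguous.
    """
    rng = config.rng(_STREAM_ASSOC)
    tfs = config.tf_labels
    diseases = config.disease_labels
    tf_disease = {tf: diseases[i] for i, tf in enumerate(tfs)}

    assoc = [TFDiseaseAssoc(tf, tf_disease[tf], source="base") for tf in tfs]
    seen = {(a.antigen, a.disease_id) for a in assoc}
    non_planted = [tf for tf in tfs if tf not in truth.planted_tfs]
    attempts = 0
    added = 0
    while added < config.n_noise_assoc and attempts < 50 * max(1, config.n_noise_assoc):
        attempts += 1
        tf = non_planted[int(rng.integers(0, len(non_planted)))]
        dis = diseases[int(rng.integers(0, len(diseases)))]
        if (tf, dis) not in seen:
            seen.add((tf, dis))
            assoc.append(TFDiseaseAssoc(tf, dis, source="noise"))
            added += 1

    standard = [
        StandardAssoc(truth.condition_id, tf_disease[tf]) for tf in truth.planted_tfs
    ]
    return assoc, standard


def write_dataset(config: SimConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Emit a complete on-disk dataset for one condition.

    Layout: ``conditions.tsv`` (condition_id, group, replicate, path),
    replicate BEDs, ``library/manifest.tsv`` + experiment BEDs,
    ``tf_disease.tsv``, ``standard.tsv`` and ``truth.json``. Byte-identical
    across reruns with the same config.
    """
    outdir = os.fspath(outdir)
    os.makedirs(os.path.join(outdir, "library"), exist_ok=True)
    exposed, control, truth = simulate_condition(config)
    library = simulate_library(config, truth)
    assoc, standard = simulate_associations(config, truth)

    cond_rows = []
    for group, reps in (("exposed", exposed), ("control", control)):
        for r, ps in enumerate(reps, start=1):
            rel = f"{config.condition_id}.{group}.rep{r}.bed"
            write_bed(ps, os.path.join(outdir, rel))
            cond_rows.append((config.condition_id, group, r, rel))
    with open(os.path.join(outdir, "conditions.tsv"), "w") as fh:
        fh.write("condition_id\tgroup\treplicate\tpath\n")
        for row in cond_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    with open(os.path.join(outdir, "library", "manifest.tsv"), "w") as fh:
        fh.write("experiment_id\tantigen\tcell_type_class\tgenome\tpath\n")
        for ps in library:
            rel = f"{ps.experiment_id}.bed"
            write_bed(ps, os.path.join(outdir, "library", rel))
            fh.write(f"{ps.experiment_id}\t{ps.antigen}\t{ps.cell_type_class}\t"
                     f"{ps.genome}\t{rel}\n")

    with open(os.path.join(outdir, "tf_disease.tsv"), "w") as fh:
        fh.write("antigen\tdisease_id\tsource\n")
        for a in assoc:
            fh.write(f"{a.antigen}\t{a.disease_id}\t{a.source}\n")
    with open(os.path.join(outdir, "standard.tsv"), "w") as fh:
        fh.write("condition_id\tdisease_id\n")
        for s in standard:
            fh.write(f"{s.condition_id}\t{s.disease_id}\n")
    truth.to_json(os.path.join(outdir, "truth.json"))
    return {
        "conditions": os.path.join(outdir, "conditions.tsv"),
        "library_manifest": os.path.join(outdir, "library", "manifest.tsv"),
        "tf_disease": os.path.join(outdir, "tf_disease.tsv"),
        "standard": os.path.join(outdir, "standard.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
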