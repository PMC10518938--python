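"""End-to-end workflow: replicate intersection -> DAR calling -> TF
enrichment -> antigen collapse -> triad matrix -> evaluation, with every
intermediate written as TSV/BED plus a provenance sidecar (config hash +
input digests) so reruns with unchanged inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .dars import DARSet, detect_dars, intersect_replicates, write_darset
from .enrichment import (
    DEFAULT_SCORE_CAP,
    collapse_by_antigen,
    enrich,
    filter_by_cell_type_class,
    write_results,
)
from .evaluation import evaluate, read_standard, write_report
from .intervals import (
    PeakSet,
    filter_by_score,
    normalize_chr_prefix,
    read_bed,
    read_library_manifest,
)
from .triads import build_triads, read_tf_disease_assoc, write_triad_matrix

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Workflow parameters.

    Defaults reproduce the published analysis settings: peak-score
    threshold 100 (MACS2 Q <= 1e-10 under the int(-10*log10 Q) convention),
    +/- 5 kb TSS flank for gene-list mode, and no cell-type-class filter.
    """

    genome: str = ""
    peak_score_threshold: int = 100
    flank: int = 5000
    score_cap: float = DEFAULT_SCORE_CAP
    cell_type_class_filter: str | None = None
    chr_normalize: bool = False
    seed: int | None = None
    log_level: str = "INFO"

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar(out_path: str, config: RunConfig, input_paths: Sequence[str]) -> None:
    prov = {
        "config_digest": config.digest(),
        "inputs": {os.path.basename(p): _sha256(p) for p in sorted(input_paths)},
    }
    with open(out_path + ".prov.json", "w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _load_conditions(
    conditions_tsv: str, config: RunConfig
) -> dict[str, dict[str, list[PeakSet]]]:
    df = pd.read_csv(conditions_tsv, sep="\t", dtype={"condition_id": str, "group": str})
    missing = {"condition_id", "group", "replicate", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"conditions table lacks columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(conditions_tsv))
    out: dict[str, dict[str, list[PeakSet]]] = {}
    for row in df.itertuples(index=False):
        if row.group not in ("exposed", "control"):
            raise ValueError(f"group must be 'exposed' or 'control', got {row.group!r}")
        path = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        ps = read_bed(
            path,
            genome=config.genome,
            experiment_id=f"{row.condition_id}.{row.group}.rep{row.replicate}",
            antigen="ATAC",
        )
        if config.chr_normalize:
            ps = dataclasses.replace(ps, intervals=normalize_chr_prefix(ps.intervals))
        out.setdefault(row.condition_id, {}).setdefault(row.group, []).append(ps)
    return out


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return wrap


def run_pipeline(
    config: RunConfig,
    conditions_tsv: str | os.PathLike,
    library_manifest: str | os.PathLike,
    tf_disease_tsv: str | os.PathLike,
    standard_tsv: str | os.PathLike,
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Run DAR calling, enrichment, triad building and evaluation.

    Writes, under ``outdir``: per-condition opened/closed DAR BEDs,
    per-condition enrichment TSVs (raw and antigen-collapsed), the triad
    matrix (long + wide), the evaluation report, and a run log with counts
    at every stage. Returns the paths of the main outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = os.fspath(outdir)
    conditions_tsv = os.fspath(conditions_tsv)
    library_manifest = os.fspath(library_manifest)
    tf_disease_tsv = os.fspath(tf_disease_tsv)
    standard_tsv = os.fspath(standard_tsv)
    for label, p in (("conditions", conditions_tsv), ("library manifest", library_manifest),
                     ("TF-disease table", tf_disease_tsv), ("standard", standard_tsv)):
        if not os.path.exists(p):
            raise PipelineError(f"stage 'inputs' failed: {label} not found at {p}")
    os.makedirs(outdir, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    conditions = _stage("inputs")(_load_conditions, conditions_tsv, config)
    library = _stage("inputs")(read_library_manifest, library_manifest)
    library = filter_by_cell_type_class(library, config.cell_type_class_filter)
    if config.peak_score_threshold > 0:
        library = [
            filter_by_score(ps, config.peak_score_threshold)
            if all(iv.score is not None for iv in ps) and len(ps)
            else ps
            for ps in library
        ]
    log(f"library: {len(library)} experiments after filtering "
        f"(threshold={config.peak_score_threshold}, "
        f"cell_type_class={config.cell_type_class_filter!r})")

    dars_dir = os.path.join(outdir, "dars")
    enr_dir = os.path.join(outdir, "enrichment")
    os.makedirs(enr_dir, exist_ok=True)
    per_condition_collapsed = {}
    for cond, groups in conditions.items():
        for group in ("exposed", "control"):
            if group not in groups:
                raise PipelineError(
                    f"stage 'dars' failed: condition {cond!r} has no {group} replicates"
                )
        log(f"condition {cond}: {len(groups['exposed'])} exposed / "
            f"{len(groups['control'])} control replicates")
        if config.peak_score_threshold > 0:
            groups = {
                g: [filter_by_score(ps, config.peak_score_threshold)
                    if all(iv.score is not None for iv in ps) and len(ps) else ps
                    for ps in reps]
                for g, reps in groups.items()
            }
        exposed_common = _stage("dars")(intersect_replicates, groups["exposed"])
        control_common = _stage("dars")(intersect_replicates, groups["control"])
        log(f"condition {cond}: {len(exposed_common)} exposed-common, "
            f"{len(control_common)} control-common regions")
        darset = _stage("dars")(
            detect_dars, exposed_common, control_common, cond, config.genome
        )
        log(f"condition {cond}: {len(darset.opened)} opened, "
            f"{len(darset.closed)} closed DARs")
        opened_bed, closed_bed = write_darset(darset, dars_dir)
        _sidecar(opened_bed, config, [conditions_tsv])
        _sidecar(closed_bed, config, [conditions_tsv])

        results = _stage("enrich")(enrich, darset, library, config.score_cap)
        collapsed = collapse_by_antigen(results)
        n_sig = sum(1 for r in collapsed if r.q_value < 0.05)
        log(f"condition {cond}: {len(results)} experiments tested, "
            f"{len(collapsed)} antigens, {n_sig} significant at q < 0.05")
        raw_path = write_results(results, os.path.join(enr_dir, f"{cond}.tsv"))
        col_path = write_results(
            collapsed, os.path.join(enr_dir, f"{cond}.collapsed.tsv")
        )
        _sidecar(raw_path, config, [conditions_tsv, library_manifest])
        _sidecar(col_path, config, [conditions_tsv, library_manifest])
        per_condition_collapsed[cond] = collapsed

    assoc = _stage("triad")(read_tf_disease_assoc, tf_disease_tsv)
    standard = _stage("evaluate")(read_standard, standard_tsv)
    matrix = _stage("triad")(
        build_triads,
        per_condition_collapsed,
        assoc,
        [s.disease_id for s in standard],
    )
    log(f"triad matrix: {len(matrix.conditions)} conditions x "
        f"{len(matrix.diseases)} diseases")
    long_path, wide_path = write_triad_matrix(
        matrix,
        os.path.join(outdir, "triads.long.tsv"),
        os.path.join(outdir, "triads.wide.tsv"),
    )
    _sidecar(long_path, config, [conditions_tsv, library_manifest, tf_disease_tsv])

    report = _stage("evaluate")(evaluate, matrix, standard)
    log(f"evaluation: mean AUROC {report.mean_auroc:.6g}, "
        f"mean AUPR {report.mean_aupr:.6g}, global AUROC {report.global_auroc:.6g}, "
        f"global AUPR {report.global_aupr:.6g}"
        + (f" (excluded: {', '.join(report.excluded_conditions)})"
           if report.excluded_conditions else ""))
    report_path = write_report(report, os.path.join(outdir, "evaluation.tsv"))
    _sidecar(report_path, config,
             [conditions_tsv, library_manifest, tf_disease_tsv, standard_tsv])

    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return {
        "dars_dir": dars_dir,
        "enrichment_dir": enr_dir,
        "triads_long": long_path,
        "triads_wide": wide_path,
        "evaluation": report_path,
        "run_log": os.path.join(outdir, "run.log"),
    }
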