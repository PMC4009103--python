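"""End-to-end orchestration: simulate/load → QC → threshold → call → map →
summarize → enrich, with a reproducibility manifest.

Every run writes a fixed set of TSV/JSON outputs plus ``run_manifest.json``
(config echo, seed, per-stage row counts, tool version). Outputs contain no
timestamps, so a run with an identical config and seed reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationConfig, CalibrationResult, calibrate
from .datatypes import (
    DmgStatus,
    GenomeLayout,
    PooledBetaSet,
    ProbeAnnotation,
    annotations_by_probe,
)
from .dmg import (
    DmgRecord,
    OverlapResult,
    dmg_status_summary,
    dmgs_to_frame,
    gene_list_overlap,
    map_dmps_to_genes,
)
from .dmp import (
    DmpCall,
    call_dmps,
    direction_split,
    dmps_to_frame,
    global_summary,
    percent_of_probes,
    region_distribution,
    window_counts,
    x_hypomethylation_analysis,
)
from .enrichment import enrich, enrichment_to_frame
from .io import (
    RetentionReport,
    filter_probes,
    read_beta_tables,
    read_gene_list,
    read_gmt,
    read_manifest,
    write_beta_table,
    write_gene_list,
    write_gmt,
    write_manifest,
)
from .simulate import (
    GeneSetConfig,
    SimulationConfig,
    default_planted_config,
    generate_gene_sets,
    generate_manifest,
    generate_pools,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of ``threshold`` / ``calibration``.

    When the input paths are all None the synthetic generator supplies the
    inputs (written under ``<outdir>/inputs/`` so the run is self-contained).
    """

    outdir: str | Path = "deltameth_run"
    mode: str = "autosomal"  # "autosomal" or "x_hypo"
    manifest_path: str | Path | None = None
    beta_male_path: str | Path | None = None
    beta_female_path: str | Path | None = None
    gene_sets_path: str | Path | None = None
    aging_genes_path: str | Path | None = None
    disease_genes_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    threshold: float | None = 0.20
    calibration: CalibrationConfig | None = None
    exclude_chroms: tuple[str, ...] = ("X", "Y")
    detp_max: float = 0.05
    window_size: int = 10_000_000
    fdr_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.threshold is None) == (self.calibration is None):
            raise ValueError(
                "exactly one of threshold / calibration must be set"
            )
        if self.mode not in ("autosomal", "x_hypo"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def echo(self) -> dict:
        # outdir is omitted: the manifest lives inside it, and recording the
        # absolute path would make otherwise identical bundles differ
        out = dataclasses.asdict(self)
        del out["outdir"]
        for key in list(out):
            if key.endswith("_path") and out[key] is not None:
                out[key] = str(out[key])
        return out


@dataclass
class PipelineResult:
    """In-memory view of everything a run computed and wrote."""

    config: PipelineConfig
    annotations: list[ProbeAnnotation]
    pools: PooledBetaSet
    retention: RetentionReport
    threshold: float
    calibration: CalibrationResult | None
    dmps: list[DmpCall]
    dmgs: list[DmgRecord]
    truth: pd.DataFrame | None
    stage_counts: dict[str, int]
    outputs: dict[str, Path]


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_tsv(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _prepare_inputs(
    config: PipelineConfig, outdir: Path
) -> tuple[
    list[ProbeAnnotation],
    PooledBetaSet,
    dict[str, tuple[str, list[str]]],
    list[str],
    list[str],
    pd.DataFrame | None,
]:
    paths = (
        config.manifest_path,
        config.beta_male_path,
        config.beta_female_path,
    )
    if any(p is not None for p in paths):
        if any(p is None for p in paths):
            raise ValueError(
                "manifest and both beta tables must be given together"
            )
        annotations = read_manifest(config.manifest_path)
        pools = read_beta_tables(config.beta_male_path, config.beta_female_path)
        terms = read_gmt(config.gene_sets_path) if config.gene_sets_path else {}
        aging = read_gene_list(config.aging_genes_path) if config.aging_genes_path else []
        disease = (
            read_gene_list(config.disease_genes_path)
            if config.disease_genes_path
            else []
        )
        return annotations, pools, terms, aging, disease, None

    sim = config.simulation or default_planted_config(seed=config.seed)
    annotations = generate_manifest(sim)
    pools, truth = generate_pools(annotations, sim)
    ann_map = annotations_by_probe(annotations)
    planted_genes = sorted(
        {
            g.upper()
            for probe_id in truth["probe_id"]
            for g in ann_map[probe_id].genes
        }
    )
    terms, aging, disease = generate_gene_sets(
        annotations,
        GeneSetConfig(enriched_genes=tuple(planted_genes), seed=sim.seed),
    )
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    write_manifest(annotations, inputs / "manifest.tsv")
    write_beta_table(
        inputs / "pool_male.tsv", pools.probe_ids, pools.beta_male, pools.detp_male
    )
    write_beta_table(
        inputs / "pool_female.tsv",
        pools.probe_ids,
        pools.beta_female,
        pools.detp_female,
    )
    write_gmt(terms, inputs / "gene_sets.gmt")
    write_gene_list(aging, inputs / "aging_genes.txt")
    write_gene_list(disease, inputs / "disease_genes.txt")
    _write_tsv(inputs / "truth.tsv", truth)
    return annotations, pools, terms, aging, disease, truth


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in fixed order and write the result bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage_counts: dict[str, int] = {}

    def emit_tsv(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        _write_tsv(path, frame)
        outputs[name] = path

    def emit_json(name: str, obj: dict) -> None:
        path = outdir / f"{name}.json"
        _write_json(path, obj)
        outputs[name] = path

    annotations, pools, terms, aging, disease, truth = _prepare_inputs(
        config, outdir
    )
    ann_map = annotations_by_probe(annotations)
    stage_counts["input_probes"] = len(pools)
    logger.info("inputs: %d probes, %d terms", len(pools), len(terms))

    # --- threshold --------------------------------------------------------
    calibration_result: CalibrationResult | None = None
    if config.calibration is not None:
        calibration_result = calibrate(config.calibration)
        threshold = calibration_result.recommended_threshold
        emit_json("calibration", calibration_result.as_dict())
        logger.info("calibration: recommended threshold %.2f", threshold)
    else:
        threshold = float(config.threshold)

    # --- QC + calling -----------------------------------------------------
    if config.mode == "x_hypo":
        dmps = x_hypomethylation_analysis(
            pools, ann_map, threshold=threshold, detp_max=config.detp_max
        )
        retention = RetentionReport(
            n_input=len(pools), n_retained=len(pools)
        )
        filtered = pools
    else:
        filtered, retention = filter_probes(
            pools,
            ann_map,
            detp_max=config.detp_max,
            exclude_chroms=set(config.exclude_chroms),
        )
        dmps = call_dmps(filtered, ann_map, threshold=threshold)
    stage_counts["retained_probes"] = retention.n_retained
    stage_counts["dmps"] = len(dmps)
    logger.info("calling: %d DMPs at |ΔMe| > %.2f", len(dmps), threshold)
    emit_tsv("dmps", dmps_to_frame(dmps))

    # --- summaries --------------------------------------------------------
    layout = GenomeLayout(window_size=config.window_size)
    if config.mode == "autosomal":
        summary = global_summary(filtered)
        emit_json(
            "global_summary",
            {
                "mean_male": summary.mean_male,
                "mean_female": summary.mean_female,
                "t_statistic": summary.t_statistic,
                "p_value": summary.p_value,
                "n_probes": summary.n_probes,
            },
        )
        beta_by_probe = {
            p: (m, f)
            for p, m, f in zip(
                filtered.probe_ids, filtered.beta_male, filtered.beta_female
            )
        }
        retained_ann = [ann_map[p] for p in filtered.probe_ids]
        emit_tsv(
            "windows_probes",
            window_counts(retained_ann, layout, beta_by_probe=beta_by_probe),
        )
    emit_tsv("region_distribution", region_distribution(dmps))
    if dmps:
        emit_tsv("windows_dmps", window_counts(dmps, layout))
    split = direction_split(dmps)
    emit_json(
        "direction_split",
        {
            "n_hyper": split.n_hyper,
            "n_hypo": split.n_hypo,
            "hyper_fraction": None if not split.total else split.hyper_fraction,
            "hypo_fraction": None if not split.total else split.hypo_fraction,
        },
    )
    emit_tsv("direction_split_by_region", split.per_region)

    # --- gene level -------------------------------------------------------
    dmgs = map_dmps_to_genes(dmps)
    stage_counts["dmgs"] = len(dmgs)
    emit_tsv("dmgs", dmgs_to_frame(dmgs))
    status = dmg_status_summary(dmgs)
    emit_json(
        "dmg_status_summary",
        {
            "n_hyper": status.n_hyper,
            "n_hypo": status.n_hypo,
            "n_mixed": status.n_mixed,
            "fractions": status.fractions() if status.total else None,
        },
    )

    universe = sorted({g.upper() for ann in annotations for g in ann.genes})
    overlaps: list[OverlapResult] = []
    for gene_list, label in ((aging, "aging"), (disease, "disease")):
        if gene_list and dmgs:
            overlaps.append(gene_list_overlap(dmgs, gene_list, label, universe))
    if overlaps:
        emit_tsv(
            "gene_list_overlaps",
            pd.concat([o.overlap for o in overlaps], ignore_index=True),
        )
        emit_json(
            "gene_list_overlap_summary",
            {
                o.label: {
                    "n_overlap": o.n_overlap,
                    "n_dmgs": o.n_dmgs,
                    "n_list": o.n_list,
                    "expected_overlap": o.expected_overlap,
                }
                for o in overlaps
            },
        )

    # --- enrichment -------------------------------------------------------
    if terms and dmgs:
        selections = {
            "hyper": [d.gene_symbol for d in dmgs if d.status is DmgStatus.HYPER],
            "hypo": [d.gene_symbol for d in dmgs if d.status is DmgStatus.HYPO],
        }
        for label, selected in selections.items():
            if not selected:
                continue
            rows, significant = enrich(
                selected, terms, universe, fdr_threshold=config.fdr_threshold
            )
            emit_tsv(f"enrichment_{label}", enrichment_to_frame(rows))
            emit_tsv(
                f"enrichment_{label}_significant",
                enrichment_to_frame(significant),
            )
            stage_counts[f"enriched_terms_{label}"] = len(significant)

    # --- run manifest + report -------------------------------------------
    emit_json(
        "run_manifest",
        {
            "tool": "deltameth",
            "version": __version__,
            "seed": config.seed,
            "config": config.echo()
            | {
                "simulation": None
                if config.simulation is None
                else dataclasses.asdict(config.simulation),
                "calibration": None
                if config.calibration is None
                else dataclasses.asdict(config.calibration),
            },
            "threshold_used": threshold,
            "stage_counts": stage_counts,
            "retention": retention.as_dict(),
        },
    )
    result = PipelineResult(
        config=config,
        annotations=annotations,
        pools=pools,
        retention=retention,
        threshold=threshold,
        calibration=calibration_result,
        dmps=dmps,
        dmgs=dmgs,
        truth=truth,
        stage_counts=stage_counts,
        outputs=outputs,
    )
    report_path = outdir / "report.md"
    report_path.write_text(make_report(result))
    result.outputs["report"] = report_path
    return result


def make_report(result: PipelineResult) -> str:
    """Human-readable markdown restating every headline statistic of a run."""
    cfg = result.config
    lines = [
        "# Pooled differential-methylation run report",
        "",
        f"- mode: {cfg.mode}",
        f"- seed: {cfg.seed}",
        f"- |ΔMe| threshold: {result.threshold:.2f}"
        + (" (calibrated)" if result.calibration else " (fixed)"),
        f"- probes in: {result.retention.n_input}; retained after QC: "
        f"{result.retention.n_retained} "
        f"(removed: {result.retention.removed_detection_p} detection-p, "
        f"{result.retention.removed_chromosome} chromosome)",
        "",
    ]
    if result.calibration is not None:
        cal = result.calibration
        lines += [
            "## Threshold calibration",
            "",
            f"- cutoff over {len(cal.per_rep_bounds)} repetitions: "
            f"{cal.cutoff_mean:.3f} ± {cal.cutoff_sd:.3f} (mean ± SD)",
            f"- recommended threshold: {cal.recommended_threshold:.2f}",
            "",
        ]
    n_retained = result.retention.n_retained
    lines += ["## Differential methylation calls", ""]
    if not result.dmps:
        lines += ["No DMPs were called at this threshold.", ""]
    else:
        pct = percent_of_probes(len(result.dmps), n_retained)
        split = direction_split(result.dmps)
        lines += [
            f"- {len(result.dmps)} DMPs ({pct}% of the {n_retained} examined probes)",
            f"- direction: {split.n_hyper} hypermethylated "
            f"({100 * split.hyper_fraction:.1f}%), {split.n_hypo} hypomethylated "
            f"({100 * split.hypo_fraction:.1f}%) in the female pool",
            "",
            "### Region distribution (unique probe–region pairs)",
            "",
        ]
        region = region_distribution(result.dmps)
        for row in region.itertuples(index=False):
            frac = "-" if pd.isna(row.fraction) else f"{100 * row.fraction:.1f}%"
            lines.append(f"- {row.region_group}: {row.count} ({frac})")
        lines.append("")
        status = dmg_status_summary(result.dmgs)
        lines += ["## Differentially methylated genes", ""]
        if status.total:
            fr = status.fractions()
            lines += [
                f"- {status.total} DMGs: {status.n_hyper} hypermethylated "
                f"({100 * fr['hyper']:.1f}%), {status.n_hypo} hypomethylated "
                f"({100 * fr['hypo']:.1f}%), {status.n_mixed} mixed "
                f"({100 * fr['mixed']:.1f}%)",
                "",
            ]
    for label in ("hyper", "hypo"):
        path = result.outputs.get(f"enrichment_{label}_significant")
        if path is None:
            continue
        table = pd.read_csv(path, sep="\t")
        lines += [f"## Enriched terms ({label}methylated DMGs, FDR < "
                  f"{cfg.fdr_threshold})", ""]
        if table.empty:
            lines += ["None.", ""]
        else:
            for row in table.head(10).itertuples(index=False):
                lines.append(
                    f"- {row.term_id} ({row.description}): overlap "
                    f"{row.overlap}/{row.term_size}, p = {row.p_value:.3g}, "
                    f"FDR = {row.fdr_adjusted_p:.3g}"
                )
            lines.append("")
    return "\n".join(lines) + "\n"
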