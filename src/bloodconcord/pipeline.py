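"""End-to-end orchestration: simulate/load -> normalize -> concordance ->
probe metrics -> enrichment, with a JSON + Markdown report.

Every stage's output is also written as a standalone TSV so stages can be
re-run or inspected independently.  With a fixed seed the whole run is
byte-identical across invocations.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import concordance as conc
from . import enrichment as enr
from . import io as bio
from . import preprocess as pp
from . import probe_metrics as pm
from .simulate import (
    SimulationConfig,
    ground_truth_to_json,
    simulate_annotation,
    simulate_experiment,
)
from .types import ExpressionMatrix

log = logging.getLogger("bloodconcord")


# ---------------------------------------------------------------- report schema

class ConcordanceBlock(BaseModel):
    platform: str
    mean_within_donor_correlation: float
    mean_across_donor_correlation: float
    sn_ratio: float
    n_within_pairs: int = Field(ge=1)
    n_across_pairs: int = Field(ge=1)


class PropertyCorrelationEntry(BaseModel):
    measure: str
    property: str
    r: float | None
    p: float | None
    significant: bool
    n: int


class EnrichmentEntry(BaseModel):
    set: str
    overlap: int
    selected_size: int
    set_in_universe: int
    universe_size: int
    p: float
    fdr: float


class PcaBlock(BaseModel):
    explained_variance_ratio: list[float]
    n_components: int


class StageLog(BaseModel):
    stage: str
    seconds: float
    details: dict[str, int | float | str] = Field(default_factory=dict)


class PipelineReport(BaseModel):
    """Machine-readable summary of one pipeline run."""

    seed: int
    n_samples: int
    n_probes: int
    parameters: dict[str, float | int | str | None]
    concordance: list[ConcordanceBlock]
    pca: PcaBlock | None = None
    property_correlations: dict[str, list[PropertyCorrelationEntry]] = Field(
        default_factory=dict
    )
    enrichment: dict[str, list[EnrichmentEntry]] = Field(default_factory=dict)
    stages: list[StageLog] = Field(default_factory=list)


# ---------------------------------------------------------------- configuration

@dataclass
class PipelineConfig:
    """What to run and where to put it.

    Either ``simulation`` is set (synthetic inputs are generated) or the
    three input paths point at existing files.
    """

    out_dir: Path
    simulation: SimulationConfig | None = None
    intensity_dir: Path | None = None
    sample_sheet: Path | None = None
    annotation: Path | None = None
    gmt: Path | None = None
    span: float = pp.DEFAULT_SPAN
    keep_fraction: float | None = None
    top_variance_fraction: float = 0.05
    alpha: float = 0.05
    run_concordance: bool = True
    run_pca: bool = True
    run_metrics: bool = True
    run_enrichment: bool = True
    plots: bool = True

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulation is None:
            for name in ("intensity_dir", "sample_sheet", "annotation"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(
                        f"{name} is required when simulation is disabled"
                    )
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")


# ---------------------------------------------------------------- stages

def _timed(stages: list[StageLog], name: str, **details):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                log.error("stage %s failed after %.2fs: %s", name, dt, exc)
                return False
            stages.append(StageLog(stage=name, seconds=round(dt, 4),
                                   details=details))
            log.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def _load_inputs(config: PipelineConfig, out: Path):
    if config.simulation is not None:
        sim = config.simulation
        annotation = simulate_annotation(sim)
        arrays, sheet, truth = simulate_experiment(sim, annotation)
        raw_dir = out / "raw"
        raw_dir.mkdir(exist_ok=True)
        for arr in arrays:
            bio.write_intensity_table(arr, raw_dir / f"{arr.sample_id}.tsv")
        bio.write_sample_sheet(sheet, out / "sample_sheet.tsv")
        bio.write_annotation(annotation, out / "annotation.tsv")
        ground_truth_to_json(truth, out / "ground_truth.json")
        return arrays, sheet, annotation
    sheet = bio.read_sample_sheet(config.sample_sheet)
    annotation = bio.read_annotation(config.annotation)
    arrays = [
        bio.read_intensity_table(
            Path(config.intensity_dir) / f"{sid}.tsv", sample_id=sid
        )
        for sid in sheet["sample_id"]
    ]
    return arrays, sheet, annotation


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the configured stages; return (and write) the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[StageLog] = []
    seed = config.simulation.seed if config.simulation is not None else 0

    with _timed(stages, "inputs"):
        arrays, sheet, annotation = _load_inputs(config, out)

    with _timed(stages, "normalize", n_arrays=len(arrays)):
        matrix = pp.normalize_experiment(
            arrays, sheet, span=config.span, keep_fraction=config.keep_fraction
        )
        bio.write_matrix(matrix.M, out / "matrix_M.tsv")
        bio.write_matrix(matrix.A, out / "matrix_A.tsv")

    platforms = list(sheet["platform"].unique())
    report = PipelineReport(
        seed=seed,
        n_samples=len(sheet),
        n_probes=len(matrix.probe_ids),
        parameters={
            "span": config.span,
            "keep_fraction": config.keep_fraction,
            "top_variance_fraction": config.top_variance_fraction,
            "alpha": config.alpha,
        },
        concordance=[],
    )

    if config.run_concordance:
        with _timed(stages, "concordance"):
            table = conc.concordance_table(matrix)
            bio.write_table(table, out / "concordance.tsv")
            report.concordance = [
                ConcordanceBlock(**row) for row in table.to_dict("records")
            ]

    if config.run_pca:
        with _timed(stages, "pca"):
            pca = conc.pca_samples(matrix, n_components=2)
            bio.write_table(
                pca.scores.reset_index(names="sample_id"), out / "pca_scores.tsv"
            )
            if config.plots:
                conc.plot_pca(pca, sheet, str(out / "pca.png"))
            report.pca = PcaBlock(
                explained_variance_ratio=[
                    float(v) for v in pca.explained_variance_ratio
                ],
                n_components=pca.n_components,
            )

    metrics_by_platform: dict[str, pd.DataFrame] = {}
    if config.run_metrics:
        with _timed(stages, "metrics", n_platforms=len(platforms)):
            for platform in platforms:
                metrics = pm.within_platform_metrics(matrix, platform)
                for other in platforms:
                    if other == platform:
                        continue
                    cross = pm.cross_platform_test(matrix, platform, other)
                    metrics[f"pval_vs_{other}"] = cross["cross_pval"]
                metrics_by_platform[platform] = metrics
                bio.write_table(
                    metrics.reset_index(names="probe_id"),
                    out / f"metrics_{platform}.tsv",
                )
                propcorr = pm.correlate_with_properties(metrics, annotation)
                bio.write_table(propcorr, out / f"propcorr_{platform}.tsv")
                report.property_correlations[platform] = [
                    PropertyCorrelationEntry(
                        measure=r["measure"], property=r["property"],
                        r=None if pd.isna(r["r"]) else float(r["r"]),
                        p=None if pd.isna(r["p"]) else float(r["p"]),
                        significant=bool(r["significant"]), n=int(r["n"]),
                    )
                    for r in propcorr.to_dict("records")
                ]
                if config.plots:
                    pm.plot_variance_vs_gc(
                        metrics, annotation, str(out / f"var_vs_gc_{platform}.png")
                    )

    if config.run_enrichment and config.run_metrics:
        with _timed(stages, "enrichment"):
            gene_sets = bio.read_gmt(config.gmt) if config.gmt else None
            universe = sorted(set(matrix.gene_map))
            for platform, metrics in metrics_by_platform.items():
                selected = enr.select_top_variance_genes(
                    metrics, matrix.gene_map,
                    fraction=config.top_variance_fraction,
                )
                pd.Series(selected, name="gene_id").to_csv(
                    out / f"top_variance_genes_{platform}.tsv",
                    sep="\t", index=False,
                )
                if gene_sets:
                    result = enr.overrepresentation_test(
                        selected, universe, gene_sets
                    )
                    bio.write_table(result, out / f"enrichment_{platform}.tsv")
                    report.enrichment[platform] = [
                        EnrichmentEntry(**{
                            k: row[k] for k in EnrichmentEntry.model_fields
                        })
                        for row in result.to_dict("records")
                    ]

    report.stages = stages
    (out / "report.json").write_text(report.model_dump_json(indent=2) + "\n")
    (out / "report.md").write_text(render_markdown(report))
    manifest = {
        "seed": seed,
        "stages": [s.stage for s in stages],
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report


def render_markdown(report: PipelineReport) -> str:
    """Human-readable counterpart of the JSON report."""
    lines = ["# bloodconcord run report", ""]
    lines.append(f"- samples: {report.n_samples}")
    lines.append(f"- probes: {report.n_probes}")
    lines.append(f"- seed: {report.seed}")
    lines.append("")
    if report.concordance:
        lines += ["## Replicate concordance (S/N)", "",
                  "| platform | within r | across r | S/N |",
                  "|---|---|---|---|"]
        for c in report.concordance:
            lines.append(
                f"| {c.platform} | {c.mean_within_donor_correlation:.3f} "
                f"| {c.mean_across_donor_correlation:.3f} | {c.sn_ratio:.3f} |"
            )
        lines.append("")
    if report.pca is not None:
        evr = ", ".join(f"{v * 100:.1f}%" for v in
                        report.pca.explained_variance_ratio)
        lines += ["## PCA", "", f"Explained variance: {evr}", ""]
    for platform, entries in report.property_correlations.items():
        sig = [e for e in entries if e.significant]
        lines += [f"## Property correlations — {platform}", "",
                  f"{len(sig)} of {len(entries)} correlations significant "
                  f"at p<0.01", ""]
    for platform, entries in report.enrichment.items():
        lines += [f"## Enrichment — {platform}", ""]
        for e in entries[:5]:
            lines.append(
                f"- {e.set}: overlap {e.overlap}/{e.selected_size}, "
                f"p={e.p:.3g}, FDR={e.fdr:.3g}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"


def report_json_schema() -> dict:
    """The JSON Schema of the pipeline report (shipped in schemas/)."""
    return PipelineReport.model_json_schema()
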