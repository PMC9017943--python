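"""End-to-end orchestration: codify -> exclude -> infer -> assess -> QC.

The stage order is fixed; no report is ever produced from a pre-exclusion
extract. Every run writes a deterministic report set (JSON plus rendered
markdown, sorted keys, no timestamps), a JSON-lines run log, and a short
per-center dashboard. A stage failure aborts the run with a stage-named
error and removes any partial outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .assessment import (
    completion_rates,
    coverage_rates,
    patient_counts_by_stratum,
    representativeness,
    DEFAULT_FLAG_THRESHOLD_PP,
)
from .exclusions import apply_exclusions
from .inference import run_inference
from .io import (
    default_catalog,
    read_catalog,
    read_extract,
    read_national_reference,
    write_extract,
)
from .qc import QCParams, qc_all, render_qc_markdown
from .regimens import DEFAULT_GAP_DAYS
from .standardize import codify_extract
from .synthetic import read_truth

STAGES = ("load", "codify", "exclusions", "inference", "assessment", "qc", "report")

EXIT_CODES = {stage: i + 2 for i, stage in enumerate(STAGES)}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    extract_path: str
    output_dir: str
    catalog_dir: str | None = None
    reference_path: str | None = None
    truth_path: str | None = None
    gap_days: int = DEFAULT_GAP_DAYS
    flag_threshold_pp: float = DEFAULT_FLAG_THRESHOLD_PP
    qc_params: QCParams = field(default_factory=QCParams)
    seed: int = 0

    @classmethod
    def from_json_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if "qc_params" in d:
            d["qc_params"] = QCParams(**d["qc_params"])
        return cls(**d)


def _dump_json(obj, path: Path, written: list[Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    written.append(path)


def _dump_text(text: str, path: Path, written: list[Path]) -> None:
    path.write_text(text, encoding="utf-8")
    written.append(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all reports to the output dir.

    Returns a run summary (also written as ``summary.json``). Identical
    config and seed produce a byte-identical report set.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log: list[dict] = []

    def logstage(stage: str, **info) -> None:
        log.append({"stage": stage, **info})

    try:
        summary: dict = {}
        stage = "load"
        catalog = (
            read_catalog(config.catalog_dir) if config.catalog_dir
            else default_catalog()
        )
        extract, load_report = read_extract(config.extract_path, catalog)
        logstage(stage, n_rows=load_report.n_rows,
                 n_records=load_report.n_records,
                 n_fatal_rows=load_report.n_fatal_rows)
        _dump_json(load_report.to_json(), outdir / "load_report.json", written)

        stage = "codify"
        extract, cod_report = codify_extract(extract, catalog)
        logstage(stage, **cod_report.drug_status_counts)
        _dump_json(cod_report.to_json(), outdir / "codification_report.json", written)

        stage = "exclusions"
        extract, flow = apply_exclusions(extract, catalog, gap_days=config.gap_days)
        logstage(stage, analyzable=flow.n_analyzable, excluded=flow.n_excluded)

        stage = "inference"
        extract, flow, audit = run_inference(extract, flow, gap_days=config.gap_days)
        logstage(stage, n_changes=len(audit),
                 r6=flow.excluded_by_rule().get("R6_stage_unresolved", 0))
        _dump_json(flow.to_json(), outdir / "flowchart.json", written)
        _dump_text(flow.render_markdown(), outdir / "flowchart.md", written)
        with open(outdir / "inference_audit.jsonl", "w", encoding="utf-8") as fh:
            for entry in audit.entries:
                fh.write(json.dumps(entry, sort_keys=True, default=str) + "\n")
        written.append(outdir / "inference_audit.jsonl")
        write_extract(extract, outdir / "analyzable_extract.csv")
        written += [outdir / "analyzable_extract.csv",
                    outdir / "analyzable_extract.csv.meta.json"]
        summary["flowchart"] = flow.to_json()

        stage = "assessment"
        if flow.n_analyzable == 0:
            warnings.warn("every patient excluded: assessment skipped",
                          stacklevel=2)
            logstage(stage, skipped=True)
            summary["assessment"] = "skipped (empty analyzable population)"
        else:
            completion = completion_rates(extract)
            _dump_json(completion.to_json(), outdir / "completion.json", written)
            _dump_text(completion.render_markdown(), outdir / "completion.md",
                       written)
            counts = patient_counts_by_stratum(extract)
            _dump_json(counts.to_dict(orient="records"),
                       outdir / "patient_counts.json", written)
            summary["completion"] = {
                var: info["rate"] for var, info in completion.rates.items()
            }
            if config.reference_path:
                reference = read_national_reference(config.reference_path)
                # cancers absent from the reference (e.g. unknown diagnosis)
                # cannot be benchmarked nationally
                counts = counts[
                    counts["cancer"].isin(reference.counts["cancer"].unique())
                ]
                coverage = coverage_rates(counts, reference)
                _dump_json(coverage.to_json(), outdir / "coverage.json", written)
                _dump_text(coverage.render_markdown(), outdir / "coverage.md",
                           written)
                repres = representativeness(
                    counts, reference,
                    flag_threshold_pp=config.flag_threshold_pp,
                )
                _dump_json(repres.to_json(), outdir / "representativeness.json",
                           written)
                _dump_text(repres.render_markdown(),
                           outdir / "representativeness.md", written)
                summary["coverage_totals"] = coverage.totals.to_dict(
                    orient="records"
                )
            logstage(stage, n_patients=extract.n_patients)

        stage = "qc"
        if config.truth_path:
            truth = read_truth(config.truth_path)
            results = qc_all(audit, truth, params=config.qc_params,
                             seed=config.seed)
            _dump_json([r.to_json() for r in results], outdir / "qc.json", written)
            _dump_text(render_qc_markdown(results), outdir / "qc.md", written)
            summary["qc"] = [r.to_json() for r in results]
            logstage(stage, n_algorithms=len(results))
        else:
            logstage(stage, skipped=True)

        stage = "report"
        _write_dashboards(extract, flow, outdir, written)
        with open(outdir / "run_log.jsonl", "w", encoding="utf-8") as fh:
            for entry in log:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")
        written.append(outdir / "run_log.jsonl")
        _dump_json(summary, outdir / "summary.json", written)
        return summary
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named rewrap
        _cleanup(written)
        raise PipelineError(stage, str(exc)) from exc


def _cleanup(written: list[Path]) -> None:
    for p in written:
        try:
            p.unlink(missing_ok=True)
        except OSError:
            pass


def _write_dashboards(extract, flow, outdir: Path, written: list[Path]) -> None:
    """One short markdown feedback sheet per center."""
    dash = outdir / "dashboards"
    dash.mkdir(exist_ok=True)
    lookup = extract.center_lookup()
    cancers = extract.patient_cancers()
    for center_id in sorted(lookup):
        cat, reg = lookup[center_id]
        keys = [k for k in cancers.index if k.startswith(f"{center_id}|")]
        lines = [
            f"# Center {center_id}",
            "",
            f"Category: {cat or 'unknown'}; region: {reg or 'unknown'}",
            f"Analyzable patients: {len(keys)}",
        ]
        by_cancer: dict[str, int] = {}
        for k in keys:
            by_cancer[cancers.loc[k]] = by_cancer.get(cancers.loc[k], 0) + 1
        for cancer, n in sorted(by_cancer.items()):
            lines.append(f"- {cancer}: {n}")
        path = dash / f"{center_id}.md"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(path)
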