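"""End-to-end pipeline: expression tables in, delay report out.

One configuration object names the input tables and analysis knobs; the
run executes differential expression, tallying, the derepression and
low-expression checks, profile summaries, delay-explainability
classification and (when an annotation is supplied) overrepresentation of
the unexplained gene sets, writing every stage's table plus a
machine-readable metadata record. Outputs are deterministic given the
inputs and configuration: re-running the same config gives byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import io as dio
from .datamodel import DOWN, UP
from .delay import (
    classify_delay_explainability,
    derepression_check,
    low_expression_dysregulated,
    profile_summary,
    tally_expression_classes,
)
from .enrichment import fisher_overrepresentation, most_specific_terms
from .stats import differential_expression

ARTIFACTS = (
    "de.tsv",
    "tally.json",
    "delay_classification.tsv",
    "profile_summary.tsv",
    "enrichment.tsv",
    "run_metadata.json",
)


@dataclass
class PipelineConfig:
    """Paths and knobs of one full analysis run.

    Thresholds default to the conventional settings of the analysis this
    pipeline reproduces: q < 0.05 significance, 1.0 FPKM testability floor,
    FPKM < 3 low-expression cut, and 0-6 h versus 6-12 h delay windows.
    """

    control_path: str
    mutant_path: str
    reference_path: str
    out_dir: str
    annotation_path: str | None = None
    edges_path: str | None = None
    n_annotated: int | None = None
    alpha: float = 0.05
    min_tested_mean: float = 1.0
    fpkm_threshold: float = 3.0
    early_window: tuple[float, float] = (0.0, 6.0)
    late_window: tuple[float, float] = (6.0, 12.0)
    aggregate: str = "mean"
    unit: str = "FPKM"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.early_window = tuple(float(v) for v in self.early_window)  # type: ignore[assignment]
        self.late_window = tuple(float(v) for v in self.late_window)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    Returns the tally/report dictionary that is also written to
    ``tally.json``. On a stage failure, partial outputs already written are
    removed and :class:`PipelineError` names the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    return wrap


def _run(config: PipelineConfig, out: Path, written: list[Path]) -> dict:
    load = _stage("load_inputs")
    control = load(
        dio.read_expression_table, config.control_path, config.unit, "control"
    )
    mutant = load(dio.read_expression_table, config.mutant_path, config.unit, "mutant")
    reference = load(dio.read_time_course, config.reference_path)
    annotation = term_names = edges = None
    if config.annotation_path:
        annotation, term_names = load(dio.read_annotation_table, config.annotation_path)
    if config.edges_path:
        edges = load(dio.read_edge_table, config.edges_path)

    de = _stage("differential_expression")(
        differential_expression,
        control,
        mutant,
        alpha=config.alpha,
        min_tested_mean=config.min_tested_mean,
    )
    n_annotated = config.n_annotated or len(de)
    tally = _stage("tally")(tally_expression_classes, de, n_annotated)
    derepression = _stage("derepression_check")(derepression_check, de, reference)
    low_n, low_pct = _stage("low_expression_filter")(
        low_expression_dysregulated, de, config.fpkm_threshold
    )
    report = _stage("delay_classification")(
        classify_delay_explainability,
        de,
        reference,
        early_window=config.early_window,
        late_window=config.late_window,
        aggregate=config.aggregate,
    )

    up_genes = [r.gene_id for r in de if r.direction == UP and r.gene_id in reference]
    down_genes = [
        r.gene_id for r in de if r.direction == DOWN and r.gene_id in reference
    ]
    profiles = {}
    for label, genes in (("up", up_genes), ("down", down_genes)):
        if genes:
            profiles[label] = _stage("profile_summary")(
                profile_summary, genes, reference
            )

    enrichment_rows = []
    if annotation is not None:
        unexplained = {
            "up_unexplained": [
                c.gene_id
                for c in report.classifications
                if c.direction == UP and not c.explained_by_delay
            ],
            "down_unexplained": [
                c.gene_id
                for c in report.classifications
                if c.direction == DOWN and not c.explained_by_delay
            ],
        }
        background = sorted(annotation)
        for label, genes in unexplained.items():
            study = [g for g in genes if g in annotation]
            if not study:
                continue
            results = _stage("enrichment")(
                fisher_overrepresentation, study, background, annotation, term_names
            )
            specific, no_hierarchy = _stage("enrichment")(
                most_specific_terms, results, edges, config.alpha
            )
            specific_ids = {r.term_id for r in specific}
            for r in results:
                enrichment_rows.append(
                    {
                        "study_set": label,
                        "term_id": r.term_id,
                        "term_name": r.term_name,
                        "k_study": r.k_study,
                        "n_study": r.n_study,
                        "K_background": r.K_background,
                        "N_background": r.N_background,
                        "fold_enrichment": r.fold_enrichment,
                        "p": r.p_value,
                        "q": r.q_value,
                        "most_specific": r.term_id in specific_ids,
                        "no_hierarchy_supplied": no_hierarchy,
                    }
                )

    # ---- write artifacts ------------------------------------------------
    def track(name: str) -> Path:
        path = out / name
        written.append(path)
        return path

    dio.write_de_table(de, track("de.tsv"))

    report_dict = {
        "tally": dataclasses.asdict(tally),
        "derepression": {
            "n_silent_upregulated": derepression.n_silent_upregulated,
            "offending_gene_ids": list(derepression.offending_gene_ids),
            "genes_without_reference": list(derepression.genes_without_reference),
        },
        "low_expression": {
            "threshold": config.fpkm_threshold,
            "n_low_expression_significant": low_n,
            "pct_of_significant": low_pct,
        },
        "delay": {
            "n_up": report.n_up,
            "n_down": report.n_down,
            "n_up_unexplained": report.n_up_unexplained,
            "n_down_unexplained": report.n_down_unexplained,
            "n_up_explained": report.n_up_explained,
            "n_down_explained": report.n_down_explained,
            "genes_without_reference": list(report.genes_without_reference),
        },
    }
    with open(track("tally.json"), "w") as fh:
        json.dump(report_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")

    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "direction": c.direction,
                "window_early_mean": c.window_early_mean,
                "window_late_mean": c.window_late_mean,
                "explained_by_delay": c.explained_by_delay,
            }
            for c in report.classifications
        ],
        columns=[
            "gene_id",
            "direction",
            "window_early_mean",
            "window_late_mean",
            "explained_by_delay",
        ],
    ).to_csv(track("delay_classification.tsv"), sep="\t", index=False)

    profile_rows = []
    for label, prof in profiles.items():
        for (a, b), med in zip(prof.bins, prof.median_expression):
            profile_rows.append(
                {
                    "gene_set": label,
                    "bin_start": a,
                    "bin_end": b,
                    "median_expression": med,
                    "n_genes": prof.n_genes,
                }
            )
    pd.DataFrame(
        profile_rows,
        columns=["gene_set", "bin_start", "bin_end", "median_expression", "n_genes"],
    ).to_csv(track("profile_summary.tsv"), sep="\t", index=False)

    pd.DataFrame(
        enrichment_rows,
        columns=[
            "study_set",
            "term_id",
            "term_name",
            "k_study",
            "n_study",
            "K_background",
            "N_background",
            "fold_enrichment",
            "p",
            "q",
            "most_specific",
            "no_hierarchy_supplied",
        ],
    ).to_csv(track("enrichment.tsv"), sep="\t", index=False)

    metadata = {
        "config": dataclasses.asdict(config),
        "versions": {
            "devdelay": _version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "row_counts": {
            "genes": control.n_genes,
            "de_records": len(de),
            "classified": len(report.classifications),
            "enrichment_rows": len(enrichment_rows),
        },
    }
    with open(track("run_metadata.json"), "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return report_dict


def _version() -> str:
    from . import __version__

    return __version__
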