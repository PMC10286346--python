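"""End-to-end orchestration: cohort -> screening -> factor structure ->
reliability/item reduction -> ROC performance, with a reproducible artifact
bundle per run."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .cohort import (
    CohortDataset,
    default_study_specs,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .config import RunConfig
from .factor import (
    assign_items,
    correlation_matrix,
    extract_components,
    factorability,
    rotate_solution,
)
from .item_screen import screen_items
from .performance import evaluate_all, score_subjects, write_performance
from .reliability import component_reliability_report, merge_scale
from .reference import published_merged_scale

logger = logging.getLogger("spascreen")

__all__ = ["RunReport", "run_pipeline", "load_or_generate"]


@dataclass
class RunReport:
    config: dict
    artifacts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "artifacts": self.artifacts,
                    "warnings": self.warnings,
                    "summary": self.summary,
                    "version": self.version,
                    "timestamp": self.timestamp,
                },
                indent=2,
            )
        )


def load_or_generate(config: RunConfig) -> CohortDataset:
    if config.cohort_path is not None:
        logger.info("reading cohort from %s", config.cohort_path)
        return read_cohort(config.cohort_path)
    groups, items = default_study_specs()
    logger.info("generating default cohort, seed=%s", config.seed)
    return generate_cohort(
        groups, items, seed=int(config.seed), factor_corr=config.factor_corr
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order and write stable-named artifacts.

    Degeneracies (constant items, non-converged rotation, undefined
    predictive values) are recorded as coded warnings, never failures.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    report.timestamp = datetime.now(timezone.utc).isoformat()

    dataset = load_or_generate(config)
    cohort_path = out / "cohort.csv"
    write_cohort(dataset, cohort_path)
    report.artifacts["cohort"] = str(cohort_path)
    report.summary["group_sizes"] = dataset.group_sizes()

    if "screen" in config.stages:
        screen = screen_items(dataset, alpha=config.alpha)
        screen.write(out / "item_screen.tsv", out / "item_screen.json")
        report.artifacts["item_screen"] = str(out / "item_screen.tsv")
        report.summary["n_discriminating_items"] = screen.n_discriminating
        for c in screen.comparisons:
            if c.result.method == "degenerate_constant":
                report.warnings.append(
                    {"code": "W_CONSTANT_ITEM", "item": c.item_id,
                     "control_group": c.control_group}
                )

    scale = None
    assignment = None
    if "factor" in config.stages:
        R = correlation_matrix(
            dataset,
            groups=config.pca_groups,
            method=config.correlation_method,
        )
        for item in R.degenerate:
            report.warnings.append({"code": "W_DEGENERATE_ITEM", "item": item})
        n_subjects = len(dataset.response_matrix(config.pca_groups))
        fact = factorability(R, n_subjects)
        sol = extract_components(R, retention=config.retention, k=config.fixed_k)
        rotated = rotate_solution(sol)
        if not rotated.converged:
            report.warnings.append({"code": "W_ROTATION_NOT_CONVERGED"})
        assignment = assign_items(rotated, config.loading_threshold)
        rotated.write(out / "factor_solution.json", out / "loadings.tsv")
        payload = assignment.to_json_dict()
        payload["factorability"] = {
            "kmo": fact.kmo,
            "bartlett_chi2": fact.bartlett_chi2,
            "bartlett_df": fact.bartlett_df,
            "bartlett_p": fact.bartlett_p,
        }
        (out / "assignment.json").write_text(json.dumps(payload, indent=2))
        report.artifacts["factor_solution"] = str(out / "factor_solution.json")
        report.artifacts["assignment"] = str(out / "assignment.json")
        report.summary["kmo"] = fact.kmo
        report.summary["bartlett_chi2"] = fact.bartlett_chi2
        report.summary["n_components"] = rotated.n_components

    if "reliability" in config.stages:
        if assignment is None:
            raise RuntimeError(
                "stage 'reliability' requires stage 'factor' (or a precomputed scale)"
            )
        rel = component_reliability_report(
            dataset,
            assignment,
            floor=config.reliability_floor,
            convergence_floor=config.convergence_floor,
        )
        rel.write(out / "reliability.tsv")
        report.artifacts["reliability"] = str(out / "reliability.tsv")
        retained = rel.retained_components
        report.summary["retained_components"] = list(retained)
        if retained:
            scale = merge_scale(
                dataset, retained, assignment, rounding_rule=config.rounding_rule
            )
            scale.write(out / "merged_scale.json")
            report.artifacts["merged_scale"] = str(out / "merged_scale.json")
            report.summary["global_alpha"] = scale.global_alpha
            report.summary["max_score"] = scale.max_score
            report.summary["cutoff"] = scale.cutoff
        else:
            report.warnings.append({"code": "W_NO_RETAINED_COMPONENTS"})

    if "performance" in config.stages:
        if scale is None:
            # scorer-only runs fall back to the published instrument
            scale = published_merged_scale(config.rounding_rule)
            report.warnings.append({"code": "W_PUBLISHED_SCALE_FALLBACK"})
        analyses = evaluate_all(dataset, scale, ci_method=config.ci_method)
        write_performance(analyses, out / "performance.json", out)
        report.artifacts["performance"] = str(out / "performance.json")
        report.summary["auc"] = {k: a.auc for k, a in analyses.items()}
        for name, a in analyses.items():
            if a.operating.degenerate:
                report.warnings.append(
                    {"code": "W_DEGENERATE_PREDICTIVE_VALUE",
                     "comparison": name,
                     "detail": list(a.operating.degenerate)}
                )

        referrals = score_subjects(dataset, scale)
        lines = ["subject_id\tgroup\tscore\treferred"]
        lines += [
            f"{r.subject_id}\t{r.group}\t{r.score}\t{int(r.referred)}"
            for r in referrals
        ]
        (out / "referrals.tsv").write_text("\n".join(lines) + "\n")
        report.artifacts["referrals"] = str(out / "referrals.tsv")

    report.write(out / "run_manifest.json")
    report.artifacts["manifest"] = str(out / "run_manifest.json")
    return report
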