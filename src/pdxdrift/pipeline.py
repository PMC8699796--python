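"""End-to-end orchestration: simulate -> panel -> drift -> authenticate.

A run writes a self-contained report bundle (genotype matrix, panel file,
manifest, pairwise concordances, drift trajectories, pooled summary,
stability calls, QC report, run log) into one output directory; every file
is re-parseable by the package's own readers and identical configs yield
identical bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .authenticate import AuthenticationThresholds, DEFAULT_THRESHOLDS, qc_report
from .drift import (
    DEFAULT_STABILITY_THRESHOLD,
    classify_stability,
    cohort_drift_summary,
    concordance,
    drift_trajectory,
)
from .io import write_manifest, write_matrix, write_panel
from .simulate import Cohort, SimulationConfig, simulate_cohort

logger = logging.getLogger("pdxdrift")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    output_dir: Path
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: AuthenticationThresholds = DEFAULT_THRESHOLDS
    stability_threshold: float = DEFAULT_STABILITY_THRESHOLD
    log_level: str = "INFO"


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        return run

    return wrap


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full synthetic-cohort analysis; return the bundle paths."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort: Cohort = _stage("simulate")(simulate_cohort)(config.simulation)

    paths: dict[str, Path] = {}

    @_stage("write-cohort")
    def write_cohort() -> None:
        ordered = list(cohort.samples.values())
        write_matrix(ordered, cohort.panel, out / "genotypes.tsv")
        write_panel(cohort.panel, out / "panel.tsv")
        write_manifest(cohort.manifest, out / "manifest.yaml")
        paths["matrix"] = out / "genotypes.tsv"
        paths["panel"] = out / "panel.tsv"
        paths["manifest"] = out / "manifest.yaml"

    write_cohort()

    @_stage("concordance")
    def pairwise() -> None:
        with open(out / "concordance.tsv", "w") as fh:
            fh.write(
                "lineage_id\tsample_a\tsample_b\tn_compared\tn_matching\t"
                "concordance\talteration_rate\n"
            )
            for lineage in cohort.lineages:
                pt = cohort.samples[lineage.patient_sample_id]
                for p in range(1, lineage.n_passages + 1):
                    s = cohort.samples[lineage.passage_sample_id(p)]
                    r = concordance(pt, s, cohort.panel)
                    fh.write(
                        f"{lineage.lineage_id}\t{r.sample_a}\t{r.sample_b}\t"
                        f"{r.n_compared}\t{r.n_matching}\t"
                        f"{r.concordance:.6f}\t{r.alteration_rate:.6f}\n"
                    )
        paths["concordance"] = out / "concordance.tsv"

    pairwise()

    @_stage("drift")
    def drift() -> None:
        trajectories = [
            drift_trajectory(lineage, cohort.samples, cohort.panel)
            for lineage in cohort.lineages
        ]
        payload = {
            t.lineage_id: {
                "cumulative": {str(k): v for k, v in t.cumulative.items()},
                "incremental": {str(k): v for k, v in t.incremental.items()},
            }
            for t in trajectories
        }
        (out / "trajectories.json").write_text(json.dumps(payload, indent=2))
        summary = {
            which: cohort_drift_summary(trajectories, which).to_dict(orient="records")
            for which in ("cumulative", "incremental")
        }
        (out / "drift_summary.json").write_text(json.dumps(summary, indent=2))
        stability = {
            lineage.lineage_id: classify_stability(
                lineage, cohort.samples, cohort.panel, config.stability_threshold
            ).value
            for lineage in cohort.lineages
        }
        (out / "stability.json").write_text(json.dumps(stability, indent=2))
        paths["trajectories"] = out / "trajectories.json"
        paths["drift_summary"] = out / "drift_summary.json"
        paths["stability"] = out / "stability.json"

    drift()

    @_stage("authenticate")
    def auth() -> None:
        report = qc_report(cohort, config.thresholds)
        (out / "qc_report.json").write_text(report.to_json())
        (out / "qc_report.txt").write_text(report.to_text())
        paths["qc_json"] = out / "qc_report.json"
        paths["qc_text"] = out / "qc_report.txt"

    auth()

    @_stage("log")
    def write_log() -> None:
        log = {
            "package": "pdxdrift",
            "version": __version__,
            "seed": config.simulation.seed,
            "n_lineages": config.simulation.n_lineages,
            "panel_size": config.simulation.panel_size,
            "stages": [
                "simulate",
                "write-cohort",
                "concordance",
                "drift",
                "authenticate",
            ],
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
        paths["log"] = out / "run_log.json"

    write_log()
    return paths
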