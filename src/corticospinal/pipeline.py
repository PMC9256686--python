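"""End-to-end orchestration: simulate → prep → connectivity → models → weights.

``run_pipeline`` executes every stage in order, writes each intermediate
table under the output directory, and produces a single JSON summary
(``report.json``) holding the activation ANOVA, the task-vs-rest
connectivity tests, the group network model fits with the swap-bootstrap
comparison, the individual weights and their EHI correlations.  Reruns with
the same config are byte-identical; any stage failure aborts with the stage
name attached.
"""

from __future__ import annotations

import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .activation import ipsilateral_m1_asymmetry, posthoc_paired, shc_anova
from .cohort import (
    CohortDataset,
    EhiCoupling,
    TruthDistribution,
    simulate_cohort,
    truth_table,
)
from .connectivity import cohort_connectivity, compare_task_rest, ec_activity_dependency
from .design import HANDS, make_design
from .group_models import (
    MODEL_DIRECT_ONLY,
    MODEL_FULL,
    bootstrap_compare,
    fit_activity_models,
    fit_group_model,
    hand_summary_table,
)
from .io import (
    PipelineConfig,
    read_design,
    read_timeseries_table,
    read_tsv,
    write_design,
    write_report,
    write_timeseries,
    write_truth,
    write_tsv,
)
from .prep import cohort_betas, mean_series_table
from .weights import cohort_individual_weights, correlate_weights_ehi

log = logging.getLogger("corticospinal")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


@_stage("simulate")
def _load_or_simulate(config: PipelineConfig) -> CohortDataset:
    if config.input_dir:
        base = Path(config.input_dir)
        design = read_design(base / "design.tsv")
        metadata = read_tsv(base / "metadata.tsv")
        return read_timeseries_table(base / "timeseries.tsv", design, metadata)
    design = make_design(
        tr_seconds=config.tr_seconds,
        n_task_blocks=config.n_task_blocks,
        n_rest_blocks=config.n_rest_blocks,
        task_block_trs=config.task_block_trs,
        rest_block_trs=config.rest_block_trs,
    )
    return simulate_cohort(
        n_participants=config.n_participants,
        design=design,
        distribution=TruthDistribution(noise_sd=config.noise_sd),
        coupling=EhiCoupling(
            weight=config.ehi_coupling_weight,
            hand=config.ehi_coupling_hand,
            r=config.ehi_coupling_r,
        ),
        seed=config.seed,
        indirect_drive=config.indirect_drive,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write tables, null dump and ``report.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = _load_or_simulate(config)
    write_design(cohort.design, out / "design.tsv")
    write_timeseries(cohort, out / "timeseries.tsv")
    write_tsv(cohort.metadata, out / "metadata.tsv")
    if cohort.truth is not None:
        write_truth(cohort.truth, out / "truth.json")
        write_tsv(truth_table(cohort.truth), out / "truth.tsv")

    betas = _run_prep(config, cohort, out)
    estimates = _run_connectivity(config, cohort, out)
    anova_report = _run_activation(betas)
    conn_report = _run_connectivity_tests(betas, estimates)
    models_report = _run_group_models(config, betas, estimates, out)
    weights_report = _run_weights(config, cohort, estimates, out)

    report = {
        "config": config.__dict__,
        "versions": {
            "corticospinal": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "design": {
            "n_trs": cohort.design.n_trs,
            "tr_seconds": cohort.design.tr_seconds,
            "n_participants": len(cohort.participants),
        },
        "activation": anova_report,
        "connectivity": conn_report,
        "group_models": models_report,
        "individual_weights": weights_report,
    }
    write_report(report, out / "report.json")
    return report


@_stage("prep")
def _run_prep(config: PipelineConfig, cohort: CohortDataset, out: Path) -> pd.DataFrame:
    betas = cohort_betas(
        cohort, highpass=config.highpass, drop_initial=config.drop_initial
    )
    write_tsv(betas, out / "betas.tsv")
    write_tsv(
        mean_series_table(cohort, order=config.zscore_order),
        out / "mean_series.tsv",
    )
    return betas


@_stage("connectivity")
def _run_connectivity(config: PipelineConfig, cohort: CohortDataset, out: Path) -> pd.DataFrame:
    estimates = cohort_connectivity(cohort, order=config.zscore_order)
    write_tsv(estimates, out / "connectivity.tsv")
    return estimates


@_stage("activation")
def _run_activation(betas: pd.DataFrame) -> dict:
    return {
        "shc_anova": shc_anova(betas),
        "posthoc": posthoc_paired(betas).to_dict(orient="records"),
        "ipsilateral_m1_asymmetry": ipsilateral_m1_asymmetry(betas).to_dict(),
    }


@_stage("connectivity-tests")
def _run_connectivity_tests(betas: pd.DataFrame, estimates: pd.DataFrame) -> dict:
    tests = {}
    for hand in HANDS:
        for role in ("contra", "ipsi"):
            for measure in ("slope", "r"):
                key = f"{hand}_{role}_{measure}_task_vs_rest"
                tests[key] = compare_task_rest(
                    estimates, hand, source_role=role, measure=measure
                ).to_dict()
        tests[f"{hand}_ec_activity_dependency"] = ec_activity_dependency(
            betas, estimates, hand
        ).to_dict()
    return tests


@_stage("model-fit")
def _run_group_models(
    config: PipelineConfig, betas: pd.DataFrame, estimates: pd.DataFrame, out: Path
) -> dict:
    summary = hand_summary_table(betas, estimates, config.model_hand)
    write_tsv(summary, out / f"summary_{config.model_hand}.tsv")
    fit1 = fit_group_model(MODEL_FULL, summary)
    fit2 = fit_group_model(MODEL_DIRECT_ONLY, summary)
    activity = fit_activity_models(summary)
    boot = bootstrap_compare(
        MODEL_FULL,
        MODEL_DIRECT_ONLY,
        summary,
        n_iterations=config.bootstrap_iterations,
        seed=config.seed + 1,
    )
    write_tsv(
        pd.DataFrame(
            {
                "iteration": np.arange(boot.n_iterations),
                "r2_model1": boot.null_r2_1,
                "r2_model2": boot.null_r2_2,
                "delta_r2": boot.null_delta,
            }
        ),
        out / "bootstrap_null.tsv",
    )
    return {
        "hand": config.model_hand,
        "model1": fit1.to_dict(),
        "model2": fit2.to_dict(),
        "activity_models": [f.to_dict() for f in activity],
        "bootstrap": boot.to_dict(),
    }


@_stage("weights")
def _run_weights(
    config: PipelineConfig, cohort: CohortDataset, estimates: pd.DataFrame, out: Path
) -> dict:
    weights = cohort_individual_weights(
        cohort, estimates, modulator=config.weight_modulator,
        order=config.zscore_order,
    )
    write_tsv(weights, out / "weights.tsv")
    correlations = pd.concat(
        [
            correlate_weights_ehi(weights, cohort.metadata, hand, holm=True)
            for hand in HANDS
        ],
        ignore_index=True,
    )
    write_tsv(correlations, out / "weights_ehi_correlations.tsv")
    return {
        "weights": weights.to_dict(orient="records"),
        "ehi_correlations": correlations.to_dict(orient="records"),
    }
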