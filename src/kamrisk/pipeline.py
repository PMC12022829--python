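"""Orchestrate simulate -> process -> cluster -> model -> power as one seeded run."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from kamrisk.clustering import ClusterSolution, cluster_windows
from kamrisk.config import RunConfig
from kamrisk.risk_models import (
    bonferroni,
    build_feature_regressions,
    fit_glmm_logistic,
    loo_cross_validation,
    lrt_pvalue,
    marginal_r2,
    observed_power,
)
from kamrisk.signal_processing import ProcessedCohort, process_cohort
from kamrisk.synthetic import Cohort, make_cohort

log = logging.getLogger("kamrisk")


def build_feature_table(
    cohort: Cohort, processed: ProcessedCohort, solution: ClusterSolution
) -> pd.DataFrame:
    """Trial-level regression design: discrete features + cluster-derived
    early-peak indicator + athlete-level injury outcome."""
    table = processed.features.copy()
    table["early_peak"] = solution.early_peak_trial_mask.astype(int)
    table["cluster"] = solution.labels
    table["true_early_peak"] = cohort.trials["true_early_peak"].to_numpy().astype(int)
    # outcome is leg-level: trials of a later-injured leg carry injured = 1
    table["injured"] = cohort.trials["leg_injured"].to_numpy().astype(int)
    athlete_injured = cohort.athletes.set_index("athlete_id")["injured"].astype(int)
    table["athlete_injured"] = athlete_injured.loc[table["athlete_id"]].to_numpy()
    return table


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage on one cohort and assemble the run report.

    With ``out_dir`` set, every intermediate artifact (cohort CSVs, window
    matrix, cluster labels, feature table) and the report JSON are persisted
    so each stage can be re-run and audited independently.
    """
    cfg = config
    cfg.generator.seed = cfg.seed
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    cohort, truth = make_cohort(cfg.generator)
    log.info("simulate: %d athletes, %d trials (%.2fs)",
             len(cohort.athletes), cohort.n_trials, time.perf_counter() - t0)
    if out is not None:
        cohort.to_dir(out / "cohort")

    t0 = time.perf_counter()
    processed = process_cohort(cohort, cfg.processing)
    log.info("process: %d windows of %d samples (%.2fs)",
             processed.windows.shape[0], processed.windows.shape[1], time.perf_counter() - t0)

    t0 = time.perf_counter()
    solution = cluster_windows(processed.windows, cfg.clustering)
    log.info("cluster: k=%d, c-index=%.3f (%.2fs)",
             solution.k, solution.c_index, time.perf_counter() - t0)

    table = build_feature_table(cohort, processed, solution)
    if out is not None:
        _persist_intermediates(out, processed, solution, table)

    t0 = time.perf_counter()
    null = fit_glmm_logistic(table, None, n_quad=cfg.modelling.n_quad)
    head = fit_glmm_logistic(table, "early_peak", n_quad=cfg.modelling.n_quad)
    head.p_lrt = lrt_pvalue(head, null)
    head.r2_marginal = marginal_r2(head, table["early_peak"].to_numpy())

    n_injured = int(cohort.athletes["injured"].sum())
    loo_block = None
    if n_injured >= 2:
        loo = loo_cross_validation(table, "early_peak", n_quad=cfg.modelling.n_quad)
        loo_block = {
            "entries": loo.entries.to_dict(orient="records"),
            "or_range": list(loo.or_range),
            "p_range": list(loo.p_range),
            "n_refits": loo.n_refits,
        }

    table1 = build_feature_regressions(
        table, n_quad=cfg.modelling.n_quad, family_size=cfg.modelling.family_size
    )
    log.info("model: OR=%.2f p=%.2g (%.2fs)",
             head.or_hat, head.p_lrt, time.perf_counter() - t0)

    power_block = None
    if cfg.modelling.run_power:
        t0 = time.perf_counter()
        power = observed_power(
            cfg.generator,
            n_sims=cfg.modelling.n_sims,
            alpha=cfg.modelling.alpha,
            seed=(cfg.seed + 1) % (2**31 - 1),
            n_quad=cfg.modelling.n_quad,
        )
        power_block = {
            "power": power.power,
            "ci95": list(power.ci95),
            "n_sims": power.n_sims,
            "alpha": power.alpha,
        }
        log.info("power: %.3f (%.2fs)", power.power, time.perf_counter() - t0)

    import kamrisk
    import scipy

    counts = np.bincount(solution.labels, minlength=solution.k + 1)[1:]
    report = {
        "config": config.to_dict(),
        "seed": cfg.seed,
        "versions": {
            "kamrisk": kamrisk.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "cohort": {
            "n_athletes": len(cohort.athletes),
            "n_injured": n_injured,
            "n_trials": cohort.n_trials,
            "true_early_peak_fraction": float(cohort.trials["true_early_peak"].mean())
            if cohort.n_trials
            else None,
        },
        "clusters": {
            "k": solution.k,
            "c_index": solution.c_index,
            "cluster_sizes": counts.tolist(),
            "early_peak_flags": solution.early_peak_flags.tolist(),
            "n_early_peak_clusters": int(solution.early_peak_flags.sum()),
            "n_early_peak_trials": int(solution.early_peak_trial_mask.sum()),
            "c_index_by_k": {str(k): v for k, v in (solution.c_index_by_k or {}).items()},
        },
        "headline": {
            "variable": "early_peak",
            "or": head.or_hat,
            "ci95": list(head.ci95) if head.ci95 else None,
            "p_lrt": head.p_lrt,
            "r2_marginal": head.r2_marginal,
            "sigma_u": head.sigma_u,
            "beta0": head.beta0,
            "beta1": head.beta1,
            "converged": head.converged,
        },
        "table1": table1.to_dict(orient="records"),
        "loo": loo_block,
        "power": power_block,
    }
    if out is not None:
        (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True))
    return report


def _persist_intermediates(out: Path, processed, solution, table) -> None:
    win = pd.DataFrame(
        processed.windows, columns=[f"s{i:02d}" for i in range(processed.windows.shape[1])]
    )
    win.insert(0, "trial_id", processed.features["trial_id"].to_numpy())
    win.to_csv(out / "windows.csv", index=False, float_format="%.6g")
    labels = pd.DataFrame(
        {
            "trial_id": processed.features["trial_id"],
            "cluster": solution.labels,
            "early_peak": solution.early_peak_trial_mask.astype(int),
        }
    )
    labels.to_csv(out / "labels.csv", index=False)
    summary = pd.DataFrame(
        solution.cluster_means, columns=[f"s{i:02d}" for i in range(solution.cluster_means.shape[1])]
    )
    summary.insert(0, "cluster", np.arange(1, solution.k + 1))
    summary.insert(1, "n_trials", np.bincount(solution.labels, minlength=solution.k + 1)[1:])
    summary.insert(2, "early_peak", solution.early_peak_flags.astype(int))
    summary.to_csv(out / "cluster_summary.csv", index=False, float_format="%.6g")
    table.to_csv(out / "features.csv", index=False, float_format="%.8g")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj
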