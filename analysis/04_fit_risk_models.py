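"""Fit the injury-risk models on the processed, clustered cohort.

Produces the headline early-peak odds ratio with its likelihood-ratio test,
the six single-predictor feature regressions with Bonferroni adjustment, and
the leave-one-injured-athlete-out robustness table.  Writes
results/models/report.json and a table mirroring the feature-regression
summary as CSV.
"""

import json
from pathlib import Path

import pandas as pd

from kamrisk.pipeline import _jsonify
from kamrisk.risk_models import (
    build_feature_regressions,
    fit_glmm_logistic,
    loo_cross_validation,
    lrt_pvalue,
    marginal_r2,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    feats = pd.read_csv(ROOT / "processed" / "processed_trials.csv")
    labels = pd.read_csv(ROOT / "clusters" / "labels.csv")
    trials = pd.read_csv(ROOT / "cohort" / "trials.csv")
    table = feats.merge(labels, on="trial_id").merge(
        trials[["trial_id", "leg_injured"]], on="trial_id"
    )
    table["injured"] = table["leg_injured"].astype(int)

    null = fit_glmm_logistic(table, None)
    head = fit_glmm_logistic(table, "early_peak")
    p = lrt_pvalue(head, null)
    r2 = marginal_r2(head, table["early_peak"].to_numpy())
    lo, hi = head.ci95
    print(f"early peak: OR = {head.or_hat:.1f} (95% CI {lo:.1f}-{hi:.1f}), "
          f"LRT p = {p:.2g}, marginal r^2 = {r2:.3f}")

    loo = loo_cross_validation(table, "early_peak")
    print(f"leave-one-out over {loo.n_refits} injured athletes: "
          f"OR range {loo.or_range[0]:.1f}-{loo.or_range[1]:.1f}, "
          f"p range {loo.p_range[0]:.2g}-{loo.p_range[1]:.2g}")

    table1 = build_feature_regressions(table)
    print(table1[["variable", "or_hat", "ci_lower", "ci_upper", "p_adjusted", "r2_marginal"]]
          .round(3).to_string(index=False))

    out = ROOT / "models"
    out.mkdir(parents=True, exist_ok=True)
    table1.to_csv(out / "feature_regressions.csv", index=False, float_format="%.6g")
    report = {
        "headline": {
            "or": head.or_hat,
            "ci95": list(head.ci95),
            "p_lrt": p,
            "r2_marginal": r2,
            "sigma_u": head.sigma_u,
        },
        "loo": {
            "entries": loo.entries.to_dict(orient="records"),
            "or_range": list(loo.or_range),
            "p_range": list(loo.p_range),
        },
        "table1": table1.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2, sort_keys=True))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
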