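#!/usr/bin/env python
"""Model SRIL risk from clinical factors and blood-dose metrics.

Reproduces the modelling sequence on the synthetic cohort: (1) a null
logistic model from baseline ALC and PTV; (2) stepwise-AIC selection of
blood-dose candidates under ten-fold cross-validation; (3) an optimal D90
cutpoint by maximally selected rank statistics; (4) a model with the
dichotomised D90 and AIC comparison against the null; (5) the dose-response
curve of SRIL probability versus blood D90.  Writes results/sril_models.json
and results/dose_response.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from lymphodose.dvh_io import read_cohort
from lymphodose.sril_models import (
    classify_sril,
    compare_aic,
    dose_response,
    fit_logistic,
    maxstat_cutpoint,
    stepwise_cv_select,
)

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "sim"
SEED = 13
CANDIDATES = ["mean_cbc_gye", "d50_gye", "d90_gye"]


def _fit_summary(fit):
    return {
        "odds_ratios": {k: round(v, 3) for k, v in fit.odds_ratios.items()},
        "ci": {
            k: [round(lo, 3), round(hi, 3)]
            for k, (lo, hi) in fit.conf_int.iterrows()
        },
        "p": {k: round(v, 4) for k, v in fit.pvalues.items()},
        "aic": round(fit.aic, 2),
        "n": fit.n,
    }


def main() -> None:
    records = read_cohort(SIM_DIR / "cohort.csv")
    metrics = pd.read_csv(ROOT / "results" / "dose_metrics.csv").set_index("patient_id")
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "baseline_alc": [r.baseline_alc for r in records],
            "ptv_per_10cc": [r.ptv_cc / 10.0 for r in records],
            "sril": [float(classify_sril(r.weekly_alc).sril) for r in records],
        }
    ).set_index("patient_id").join(metrics, how="inner")
    base = ["baseline_alc", "ptv_per_10cc"]

    null_fit = fit_logistic(df[base], df["sril"])
    selected = stepwise_cv_select(df, df["sril"], candidates=CANDIDATES, base_terms=base, seed=SEED)
    chosen = [c for c in selected if c in CANDIDATES]

    report = {"null_model": _fit_summary(null_fit), "stepwise_selected": chosen}
    fits = [null_fit]
    for var in chosen or ["d90_gye"]:
        cut = maxstat_cutpoint(df[var].to_numpy(), df["sril"].to_numpy(), variable=var)
        ind = f"{var}_high"
        df[ind] = (df[var] > cut.cutpoint).astype(float)
        fit = fit_logistic(df[base + [ind]], df["sril"])
        fits.append(fit)
        report.setdefault("cutpoint_models", {})[var] = {
            "cutpoint_gye": round(cut.cutpoint, 3),
            "maxstat_statistic": round(cut.statistic, 3),
            **_fit_summary(fit),
        }
    ranked, best = compare_aic(fits)
    report["aic_ranking"] = [round(f.aic, 2) for f in ranked]
    report["best_model_terms"] = best.terms

    curve_var = "d90_gye"
    cont_fit = fit_logistic(df[base + [curve_var]], df["sril"])
    report["continuous_d90_model"] = _fit_summary(cont_fit)
    grid = np.linspace(df[curve_var].min(), df[curve_var].max(), 60)
    curve = dose_response(cont_fit, curve_var, grid)
    curve.round(4).to_csv(ROOT / "results" / "dose_response.csv", index=False)

    (ROOT / "results" / "sril_models.json").write_text(json.dumps(report, indent=2))
    print(f"SRIL prevalence: {df['sril'].mean():.3f} (n={len(df)})")
    print(f"stepwise-selected dose metrics: {chosen}")
    for var, m in report.get("cutpoint_models", {}).items():
        print(
            f"{var}: cutpoint {m['cutpoint_gye']} GyE, "
            f"OR(high) {m['odds_ratios'][var + '_high']}, AIC {m['aic']} "
            f"(null AIC {report['null_model']['aic']})"
        )


if __name__ == "__main__":
    main()
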