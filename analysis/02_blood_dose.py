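#!/usr/bin/env python
"""Accumulate blood dose for every patient and tabulate bDVH metrics.

Runs the circulation + dose Monte Carlo per patient (2 beams x 60 s per
fraction, 30 fractions) on the cohort from 01_simulate_cohort.py and writes
one metrics row per patient (blood mean/Dx/V_t plus lung and heart metrics)
to results/dose_metrics.csv.  2,000 blood elements per patient keep the
Monte-Carlo standard error of the mean blood dose below ~0.02 GyE while the
full cohort runs in about a minute.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lymphodose.circulation import build_default_model
from lymphodose.dose_engine import BeamSchedule, CoursePlan, accumulate_course
from lymphodose.dvh_io import read_dvh_table
from lymphodose.metrics import metrics_table

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "sim"
SEED = 12
N_ELEMENTS = 2000


def main() -> None:
    dvhs = read_dvh_table(SIM_DIR / "dvh.csv")
    model = build_default_model(None)
    schedule, course = BeamSchedule(n_beams=2, beam_on_s=60.0), CoursePlan(30)

    pids = sorted({pid for pid, _ in dvhs})
    dists = {}
    for i, pid in enumerate(pids):
        organ_dvhs = {organ: d for (p, organ), d in dvhs.items() if p == pid}
        dists[pid] = accumulate_course(
            model, organ_dvhs, schedule, course,
            seed=np.random.SeedSequence(SEED, spawn_key=(i,)),
            n_elements=N_ELEMENTS,
        )

    table = metrics_table(dists, dvhs)
    out = ROOT / "results" / "dose_metrics.csv"
    table.round(4).to_csv(out, index=False)
    med = table[["mean_cbc_gye", "d10_gye", "d50_gye", "d90_gye"]].median()
    print(f"wrote blood-dose metrics for {len(pids)} patients to {out}")
    print("cohort medians (GyE):")
    print(med.round(2).to_string())


if __name__ == "__main__":
    main()
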