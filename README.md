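# lymphodose

Radiation dose to circulating blood and the risk of severe radiation-induced
lymphopenia (SRIL) in thoracic chemoradiotherapy.

Lymphocytes are among the most radiosensitive cells in the body, and thoracic
radiotherapy inevitably irradiates the blood flowing through the lungs and
heart. Severe treatment-phase lymphopenia is associated with worse survival,
yet standard organ dose–volume histograms (DVHs) only indirectly describe the
dose the *blood* receives. This package implements a time-dependent
computational pipeline for radiation oncology researchers:

1. **Blood circulation Monte Carlo** — circulating blood is discretised into
   100,000 equal elements (5.3 L at 0.053 mL per element) that cycle through a
   heart → lungs → remainder compartment chain with ICRP reference-adult
   blood-volume fractions; mean transit time through compartment *c* is
   *f<sub>c</sub>·V/CO*.
2. **Dose accumulation** — during each 60 s beam, an element visiting the
   heart or lungs accrues a voxel dose drawn from that organ's per-fraction
   differential DVH, weighted by the fraction of beam-on time covered;
   fractions (default 30, for 66 GyE) are summed with independent paths.
3. **Blood DVH metrics** — the bDVH (fraction of blood receiving ≥ each dose)
   and its scalars: mean, D*x*% (dose to the hottest *x*% of blood),
   V<sub>*x*GyE</sub>, plus organ metrics and BED = *nd*(1 + *d*/(α/β)).
4. **SRIL modelling** — SRIL is ≥ 2 weekly absolute lymphocyte counts (ALC)
   < 200/µL during treatment. Logistic regression with Wald intervals and
   AIC, stepwise-AIC selection under ten-fold cross-validation, optimal
   cutpoints by maximally selected rank statistics, and dose–response curves.
5. **Survival** — Kaplan–Meier, log-rank, and Cox regression (Efron ties)
   for overall and progression-free survival stratified by SRIL.
6. **Synthetic cohorts** — a generator emulating a 201-patient photon
   (IMRT, n = 164) vs proton (PBSPT, n = 37) cohort, either with exactly
   known logistic/survival truth (`parametric`) or with lymphopenia emerging
   from an exponential ALC-depletion law (`mechanistic`), so every
   statistical stage can be validated without patient data.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on a synthetic
cohort (intermediate files under `scratch/`, tables under `results/`):

```bash
python analysis/01_simulate_cohort.py   # cohort + organ DVHs
python analysis/02_blood_dose.py        # circulation MC -> bDVH metrics
python analysis/03_sril_models.py       # logistic / cutpoint / AIC models
python analysis/04_survival.py          # KM, log-rank, Cox by SRIL
```

Output from a run at the default settings:

```
overall SRIL incidence: 0.333 (67/201 patients)       # IMRT 0.402, PBSPT 0.027
cohort medians (GyE):  mean_cbc 2.97  d10 3.52  d50 2.96  d90 2.44
stepwise-selected dose metrics: ['d90_gye']
d90_gye: cutpoint 2.585 GyE, OR(high) 30.312, AIC 152.77 (null AIC 217.09)
OS:  3-yr 40.0% (SRIL) vs 70.4% (no SRIL), log-rank p=0.0075, Cox HR(SRIL)=1.38
PFS: 3-yr  3.7% (SRIL) vs 13.7% (no SRIL), log-rank p=0.00012, Cox HR(SRIL)=1.85
```

Reading: proton patients receive a markedly lower blood dose and almost never
develop SRIL; among blood-dose metrics, D90% (the dose to the coldest-but-90%
of blood) is the selected predictor, its maxstat cutpoint lands near 2.6 GyE,
and dichotomising at that cutpoint improves the model AIC over the
clinical-only null; SRIL carries the configured survival disadvantage. The
dichotomised odds ratio is larger than in clinical data because the synthetic
depletion mechanism links dose to lymphopenia more tightly than reality does.

A `lymphodose` console script exposes the same stages
(`simulate-cohort`, `blood-dose`, `metrics`, `sril-fit`, `survival`).

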