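"""Fit and validate the immune-related risk score on a synthetic cohort.

Simulates a 553-patient cohort whose hazard depends log-linearly on 10 of
35 candidate descriptors, splits it 70/30 with event stratification, fits
the IRRS (univariate screen -> CV LASSO-Cox -> ln(HR) weights -> optimal
cutpoint) on the training cohort only, and validates on the held-out test
cohort.
"""

import warnings

import spatialtme as st
from spatialtme.synthetic import make_irrs_study_cohort

patients, truth = make_irrs_study_cohort(n_patients=553, seed=1)
print(f"cohort: {len(patients)} patients, "
      f"{patients['event'].sum()} events "
      f"({100 * patients['event'].mean():.1f}%)")
s = st.cohort_summary(patients)
print(f"median DFS {s['median_dfs_days']:.0f} d; 1/3/5-year recurrence "
      f"{s['recurrence_rate_365d']:.1f}/{s['recurrence_rate_1095d']:.1f}/"
      f"{s['recurrence_rate_1825d']:.1f}%")

train, test = st.stratified_split(patients, train_fraction=0.7, seed=1)
print(f"stratified split: {len(train)} train / {len(test)} test")

candidates = [c for c in patients.columns if c.startswith("feat_")]
model = st.fit_irrs(train, candidates, seed=1)
hits = len(set(model.variables) & set(truth))
print(f"\nselected {len(model.variables)} of {len(candidates)} candidates "
      f"({hits}/{len(truth)} truly prognostic); cutoff {model.cutoff:.3f}")

covars = ["sex", "age", "t_stage", "n_stage", "vascular_embolus",
          "lymph_nodes_dissected"]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = st.evaluate_irrs(model, test, covariates=covars,
                           train_time=train["time_days"],
                           train_event=train["event"])
lo, hi = res["hr_ci"]
print(f"\ntest cohort: log-rank p = {res['logrank_p']:.2e}")
print(f"adjusted HR high vs. low IRRS = {res['hr_high_vs_low']:.2f} "
      f"(95% CI {lo:.2f}-{hi:.2f})")
print("time-dependent AUC: " + ", ".join(
    f"{h // 365}y {a:.3f}" for h, a in res["auc"].items()))
print(
    "\nAn HR well above 1 with a tiny log-rank p shows the score, learned\n"
    "entirely on the training cohort, transfers to unseen patients; AUCs\n"
    "near 0.9 reflect the strong simulated effects."
)
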