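"""SID-MRM absolute quantification: calibration, LOQ, concentrations, ROC.

A base-3 dilution series of light peptide against a constant heavy spike
is fitted in log3-log3 space; the LOQ is found under the CV < 20% /
R > 0.99 rules; then a 70-cancer / 30-control cohort's light/heavy ratios
are converted to absolute serum concentrations and scored by t test, ROC
and a logistic panel.
"""

import numpy as np

from seroquant import (
    MRMSimConfig,
    absolute_concentration,
    cohort_stats,
    compute_ratios,
    determine_loq,
    fit_calibration,
    generate_mrm_dataset,
)
from seroquant.mrm import records_to_frame

sim = generate_mrm_dataset(
    MRMSimConfig(true_conc_fmol=50.0, spike_heavy_fmol=50.0, group_fold=2.0,
                 n_noisy_points=2, noisy_cv=0.4, n_replicates=10, seed=9)
)
curve = fit_calibration(sim.dilution, peptide="HQFLLTGDTQGR", transition_id="y8")
loq = determine_loq(curve)
print(f"calibration: slope {curve.slope:.3f}, R = {curve.pearson_r:.4f}, "
      f"anchor ratio {curve.points['mean_ratio'].iloc[curve.anchor_index]:.3f}")
print(f"LOQ: {loq:.2f} fmol on column (planted knee at "
      f"{sim.truth['loq_knee_fmol']:.2f} fmol)")

ratios = compute_ratios(sim.cohort)
records = [
    absolute_concentration(float(r.ratio), curve, sample_id=r.sample_id,
                           protein="A1BG", group=r.group)
    for r in ratios.itertuples()
]
report = cohort_stats(records_to_frame(records))
row = report.per_protein.iloc[0]
print(f"\ncohort (70 NSCLC / 30 control), A1BG serum concentration:")
print(f"  mean cancer / control: {row.mean_cancer:.1f} / {row.mean_control:.1f} ug/mL "
      f"(fold {row.fold_cancer_vs_control:.2f}, planted 2.0)")
print(f"  t test p = {row.p_value:.2e}")
print(f"  AUC = {row.auc:.3f} (95% CI {row.auc_ci_low:.3f}-{row.auc_ci_high:.3f})")
print("\nThe inverted calibration line turns area ratios into fmol on column")
print("and ug/mL of serum; the recovered fold and AUC quantify how well the")
print("assay separates cancer from control sera.")
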