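"""Full detection loop on a synthetic cohort, with biomarker ranking.

Scores are thresholded in a trailing 7-day window with the robust z rule;
alerts are validated against weak labels inside a -10/+7-day soft buffer, and
the sorted CMP stacks yield each patient's leading digital biomarker.
"""

import dataclasses

from contextprofile import (ThresholdConfig, biomarker_contributions,
                            cohort_biomarkers, detect, evaluate_cohort,
                            evaluate_patient, mdcmp_artifacts, score_contexts)
from contextprofile.config import RunConfig
from contextprofile.pipeline import cohort_features

cfg = RunConfig(seed=3)
cfg.synth = dataclasses.replace(cfg.synth, n_patients=6, n_days=365,
                                uti_episodes_per_patient=2,
                                hosp_episodes_per_patient=1)
feats, labels = cohort_features(cfg)

per_patient, reports = [], []
for fs, lb in zip(feats, labels):
    stacked, _, k_used, layer = mdcmp_artifacts(fs, cfg.context, 1)
    ss = score_contexts(layer, fs.frame.index, fs.patient_id, "mdcmp_equal")
    alerts = detect(ss, ThresholdConfig(method="robust_z", window_days=7, z_thr=1.65))
    per_patient.append(evaluate_patient(alerts, lb, fs.observed_days))
    reports.append(biomarker_contributions(stacked, k_used))

rep = evaluate_cohort(per_patient)
print(f"mean recall:        {rep['mean_recall_pct']:.1f}%")
print(f"mean alerts raised: {rep['mean_alerts']:.1f} "
      f"({rep['mean_alert_rate_pct']:.1f}% of observed days)")
print(f"patients with >1/3 of events recalled: "
      f"{rep['patients_above_third_recall']}/{rep['n_patients']}")

print("\ncohort digital-biomarker ranking (median share of top slots):")
print(cohort_biomarkers(reports)["median_contribution"].round(3).to_string())
print("\nHigh recall at a single-digit alert rate, with night bathroom "
      "activity as the dominant biomarker, is the expected picture for "
      "UTI-like episodes.")
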