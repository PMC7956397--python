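"""Validate the classifier against ground-truth annotations on a cohort.

Simulates ten noise-controlled subjects, classifies each with the optimized
posture-first settings, compares window-by-window against the reference
events, and prints the cohort median (Q1–Q3) of each performance metric.
"""

from hfital import AlgorithmParams, cohort_summary, run_pipeline, simulate_cohort, subject_report

subjects = simulate_cohort(10, "well_separated", seed=2021)
reports = []
for subj in subjects:
    labels, _ = run_pipeline(subj.recording, AlgorithmParams.hfital())
    reports.append(subject_report(labels, subj.truth))

summary = cohort_summary(reports)
print(f"cohort of {summary.n_subjects} subjects, optimized settings (4 s / 4.3 cps / 0.8 g)")
header = f"{'category':<12} {'sens%':>8} {'spec%':>8} {'acc%':>8} {'PE%':>8} {'APE%':>8}"
print(header)
for cat in ("sedentary", "standing", "dynamic", "total", "transitions"):
    row = [summary.get(cat, m).median for m in
           ("sensitivity_pct", "specificity_pct", "accuracy_pct", "pe_pct", "ape_pct")]
    print(f"{cat:<12} " + " ".join(f"{v:8.1f}" for v in row))

# With well-separated gait amplitudes and near-zero noise every metric is
# exact: 100% sensitivity/specificity/accuracy and 0% error for all
# activities and for the postural transitions. Degrade the scenario (see
# example 04) and standing is the first class to suffer.
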