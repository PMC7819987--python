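"""Run the full matched-cohort study on a simulated development cohort.

Reproduces the complete workflow: eligibility, propensity-score
estimation, greedy 1:1 caliper matching, balance assessment, the
odds-ratio ladder, the multiple-hematoma sensitivity analysis, and the
ROC comparison of candidate predictors.
"""

from fuzzyct import StudyConfig, run_study

report = run_study(StudyConfig(seed=1))

m = report.matching
print(
    f"cohort: {report.eligibility['n_eligible']} eligible patients, "
    f"sign prevalence {m['sign_prevalence']:.1%}, "
    f"expansion incidence {m['expansion_incidence']:.1%}"
)
print(f"matched pairs: {m['n_pairs']} (caliper {m['caliper']})")

worst = max(r["smd_after_pct"] for r in report.balance)
print(f"worst post-matching standardized difference: {worst:.1f}%")

print("\nodds ratios for sign -> expansion:")
for row in report.effect_table:
    print(
        f"  {row['method']:24s} OR {row['odds_ratio']:6.2f} "
        f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f})"
    )

print("\nsensitivity analysis (>=3 hematomas only):")
for row in report.sensitivity_table:
    if "odds_ratio" in row:
        print(
            f"  {row['method']:24s} OR {row['odds_ratio']:6.2f} "
            f"(95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f})"
        )

print("\nROC comparison (pre-matched cohort):")
for name, entry in report.roc.items():
    print(
        f"  {name:20s} AUC {entry['auc']:.2f} "
        f"({entry['ci_low']:.2f}-{entry['ci_high']:.2f})"
    )

# The crude OR overstates the matched (pair-conditional) OR because the
# sign is confounded by baseline volume, arterial pressure, location and
# associated hemorrhages; matching on the propensity score removes that
# imbalance, and the sign remains by far the strongest predictor.
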