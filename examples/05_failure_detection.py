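"""Uncertainty-based failure detection, end to end.

Runs a reduced version of the scaled study: train on phantoms spanning
mild-to-moderate corruption, test on a cohort containing severely corrupted
(out-of-domain) cases, then fit the failure-detection model -- MAD-based
Dice outlier thresholds (k = -2 "inaccurate", k = -3 "failed"), the
DC ~ uncertainty regression, its inverted uncertainty cut-offs, and AUROC.
Finally the fitted model screens cases *without* looking at ground truth.

Runtime: a few minutes on one CPU (it trains a network).  For the
full-size frozen study use scripts/acceptance.py.

Run:  python examples/05_failure_detection.py
"""

import numpy as np

from mskseg.experiments import ExperimentConfig, run_failure_detection_experiment
from mskseg.failure import screen_unlabeled

# reduced cohort sizes so the example stays snappy; all other study
# conditions (grid, corruption ranges, T=10, dropout 0.2) are the defaults
cfg = ExperimentConfig(n_train=8, n_test=12, n_corrupt=5, n_iterations=500, seed=0)
run = run_failure_detection_experiment(cfg)

records = run["records"]
print(f"{len(records)} structure records from {cfg.n_test} test phantoms "
      f"({cfg.n_corrupt} severely corrupted)")
print(f"mean Dice  clean: {run['mean_dc_uncorrupted']:.3f}   "
      f"corrupted: {run['mean_dc_corrupted']:.3f}")

fm = run["failure_model"]
print(f"\nDice thresholds: median {fm.dc_median:.3f}, MAD {fm.dc_mad:.3f}")
print(f"  inaccurate (k=-2): DC < {fm.dc_threshold_k2:.3f}")
print(f"  failed     (k=-3): DC < {fm.dc_threshold_k3:.3f}")
print(f"regression DC = {fm.regression_intercept:.3f} + {fm.regression_slope:.3f} * u"
      f"  (rho = {fm.pearson_rho:.3f})")
print(f"uncertainty cut-offs: inaccurate > {fm.uncertainty_threshold_k2:.4f}, "
      f"failed > {fm.uncertainty_threshold_k3:.4f}")
print(f"record-level AUROC: k=-2 {fm.auroc_k2}, k=-3 {fm.auroc_k3}")

fm_cases = run["failure_model_cases"]
print(f"case-level AUROC (all-structures average): k=-2 {fm_cases.auroc_k2}, "
      f"k=-3 {fm_cases.auroc_k3}")

# -- screening "unannotated" cases with the case-level model ----------------
# each case maps structure-instance index -> predictive uncertainty
case_unc = {
    subj: {i: float(u) for i, u in enumerate(g["uncertainty"])}
    for subj, g in records.groupby("subject")
}
report = screen_unlabeled(case_unc, fm_cases)
flags = {}
for r in report:
    flags.setdefault(r["flag"], []).append(r["case"])
print("\nscreening verdicts (no ground truth used):")
for flag in ("ok", "inaccurate", "failed"):
    print(f"  {flag:10s}: {len(flags.get(flag, []))} cases")

# sanity: flagged cases should indeed have lower Dice
cases = run["case_records"].set_index("subject")
flagged = [c for f in ("inaccurate", "failed") for c in flags.get(f, [])]
ok = flags.get("ok", [])
if flagged and ok:
    print(f"\nmean case Dice: flagged {cases.loc[flagged, 'dc'].mean():.3f}, "
          f"passed {cases.loc[ok, 'dc'].mean():.3f}")
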