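"""Evaluate the signature as a response and survival biomarker.

ROC for immunotherapy response, Kaplan-Meier/log-rank survival
stratification, the optimized-cutoff scan, and the small clinical formulas.
"""

import pandas as pd

from sig2screen import outcomes, simulate

# response: high signature score predicts non-response
resp, _ = simulate.gen_response(200, auc_target_slope=1.5, seed=3)
roc = outcomes.roc_auc(resp["score"], 1 - resp["response"])
print(f"response-prediction AUC = {roc.auc:.3f} (n = {len(resp)})")

# survival: high-signature group with hazard ratio 2
surv, _ = simulate.gen_survival(200, hazard_ratio=2.0, censor_rate=0.2, seed=4)
km = outcomes.km_estimate(surv)
lr = outcomes.logrank(surv)
print(f"log-rank chi2 = {lr['chi2']:.1f}, p = {lr['p_value']:.2g}")
print(f"median-ish survival probes: high S(t1)={km['high'].survival[0]:.2f}, "
      f"low S(t1)={km['low'].survival[0]:.2f}")

cut = outcomes.best_cutoff(surv, n_permutations=100, seed=0)
print(f"best cutoff {cut['cutoff']:.2f}: minimized p = {cut['p_at_cutoff']:.2g} "
      f"(optimized; permutation-adjusted p = {cut['permutation_p']:.2g})")
# The scan minimizes p over candidate cutoffs, so p_at_cutoff is biased; the
# permutation p is the honest version.

print(f"H-score 40/30/20/10 -> {outcomes.h_score([40, 30, 20, 10])}")
print(f"tumor volume (5 mm x 10 mm) -> {outcomes.tumor_volume(5, 10)} mm^3")
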