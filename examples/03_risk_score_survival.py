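"""LASSO-Cox radiomic risk score on a synthetic delta-feature cohort.

Plants 3 prognostic delta features among 200 noise features, selects with
L1-penalized Cox regression (lambda by cross-validated partial-likelihood
deviance), builds the radiomic risk score RRS = sum_j beta_j x_ij, splits
at the training median and evaluates the held-out half.
"""

import numpy as np
import pandas as pd

from deltarad.survival import (compute_rrs, concordance_index, cox_fit,
                               fit_lasso_cox, km_logrank, stratify_by_cutoff)

rng = np.random.default_rng(0)
n = 200
X = pd.DataFrame(rng.standard_normal((n, 203)),
                 columns=[f"planted{i}" for i in range(3)]
                 + [f"noise{i}" for i in range(200)])
hazard = 0.05 * np.exp(1.5 * X.iloc[:, :3].sum(axis=1))
clinical = pd.DataFrame({"os_months": rng.exponential(1 / hazard),
                         "event": np.ones(n, int)})

train, val = slice(0, 100), slice(100, 200)
model = fit_lasso_cox(X[train], clinical[train], n_folds=5, seed=0)
print(f"lambda = {model.lambda_:.4f}; selected {len(model.features)} features:")
print("  " + ", ".join(model.features[:8]) + (" ..." if len(model.features) > 8 else ""))

rrs_val = compute_rrs(model, X[val])
val_clin = clinical[val].reset_index(drop=True)
c = concordance_index(rrs_val, val_clin)
groups = stratify_by_cutoff(rrs_val.to_numpy(), model.rrs_cutoff)
km = km_logrank(groups, val_clin)
fit = cox_fit(pd.DataFrame({"rrs": rrs_val.to_numpy()}), val_clin)
hr = fit.summary.iloc[0]
print(f"validation C-index = {c:.2f}")
print(f"RRS hazard ratio = {hr['hr']:.2f} (95% CI {hr['ci_lower']:.2f}-"
      f"{hr['ci_upper']:.2f}), p = {hr['p']:.2g}")
print(f"median survival: high-risk {km.median_survival['high']:.1f} vs "
      f"low-risk {km.median_survival['low']:.1f} months "
      f"(log-rank p = {km.logrank_p:.2g})")
# A C-index well above 0.5 and a shorter high-risk median survival show the
# selected delta features carry the planted prognostic signal.
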