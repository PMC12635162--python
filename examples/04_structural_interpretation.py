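"""Explain the PET asymmetry index from structural features.

Fits the spline additive model to a 30-subject cohort in which
hippocampal volume is the strongest structural driver of the PET AI,
then attributes predictions with exact Shapley values, cross-validates
(5-fold, repeated), and checks the actual-vs-predicted correlation.
"""

import numpy as np

from pnms import (
    cross_validate,
    fit_additive_model,
    partial_dependence,
    prediction_correlation,
    shapley_importance,
)
from pnms.interpret import STRUCTURAL_FEATURES
from pnms.synthetic import simulate_structure_cohort

cohort = simulate_structure_cohort(n=30, seed=3)
X, y = cohort[STRUCTURAL_FEATURES], cohort.pet_ai.to_numpy()

shap = shapley_importance(X, y)
print("mean |Shapley| per feature (larger = more predictive):")
for name, v in shap.mean_abs.sort_values(ascending=False).items():
    print(f"  {name:>18s}: {v:.4f}")
print(f"top feature: {shap.top_feature()}  (planted: hippo_volume_ipsi)")

cv = cross_validate(X, y, k=5, iterations=200, seed=3)
r, p = prediction_correlation(cv.actual, cv.prediction)
print(f"\ncross-validated actual-vs-predicted Pearson r = {r:.2f} (P = {p:.3g})")

fit = fit_additive_model(X, y)
grid = np.linspace(X.hippo_volume_ipsi.min(), X.hippo_volume_ipsi.max(), 5)
pd_curve = partial_dependence(fit, X, "hippo_volume_ipsi", grid)
print("\npartial dependence of predicted AI on hippocampal volume (mm^3):")
for g, v in zip(pd_curve.grid, pd_curve.pd):
    print(f"  {g:8.0f} -> {v:+.4f}")
print("a rising curve means smaller hippocampi carry more negative (worse) AI.")
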