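"""The study's evaluation statistics on a worked example.

Shows the ratio-of-sums R^2, the n-1 RMSE, and the 1 x IQR boxplot
statistics, including where the R^2 form departs from the conventional
coefficient of determination.
"""

import numpy as np

from mincenet.evaluation import boxplot_stats, r_squared, rmse

actual = np.array([0.1, 0.2, 0.3, 0.4])
pred = np.array([0.15, 0.25, 0.25, 0.35])

print(f"R^2  (ratio-of-sums form)  = {r_squared(pred, actual):.4f}")
print(f"RMSE (n-1 divisor)         = {rmse(pred, actual):.5f} g/g")

wild = np.array([-0.5, 0.9, -0.3, 1.2])
print(f"\noverdispersed predictions score R^2 = {r_squared(wild, actual):.2f} (> 1!) "
      "- this form rewards matching the spread, not the residuals,")
print("which is why model comparisons in this package use 1 - SSres/SStot alongside it.")

values = [0.09, 0.11, 0.10, 0.12, 0.10, 0.13, 0.19]
s = boxplot_stats(values)
print(f"\nboxplot of predictions at true ratio 0.10: "
      f"Q1={s.q1:.3f} Q2={s.q2:.3f} Q3={s.q3:.3f} IQR={s.iqr:.3f}")
print(f"whiskers at 1 x IQR: [{s.whisker_min:.3f}, {s.whisker_max:.3f}]; "
      f"outliers: {list(s.outliers)}")
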