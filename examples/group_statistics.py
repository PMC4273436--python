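"""Statistical procedures used on grouped behavioral outcomes.

Compares exit-direction counts between genotypes with the test of equal
proportions plus a Šidák family correction, runs the Kruskal-Wallis/Dunn
workflow on preference indices, and correlates two indices.
"""

import numpy as np

from flyvalence import (
    dunn_sidak,
    equal_proportions_test,
    kruskal_wallis_dunn,
    rank_correlation,
)

# exits to light out of filtered dark-side entries, control vs two drivers
successes = [210, 60, 150]
totals = [260, 240, 250]
res = equal_proportions_test(successes, totals)
print(f"equal proportions: chi2 = {res.statistic:.1f}, df = {res.df}, "
      f"p = {res.pvalue:.2e}")
print(f"Sidak-adjusted for a family of 3: {dunn_sidak(res.pvalue, 3):.2e}")

rng = np.random.default_rng(0)
control = rng.normal(0.0, 0.15, 20)
driver_a = rng.normal(0.0, 0.15, 18)
driver_b = rng.normal(-0.45, 0.15, 16)  # clear aversive phenotype
kw = kruskal_wallis_dunn([control, driver_a, driver_b], control=0)
print(f"Kruskal-Wallis H = {kw.statistic:.1f}, p = {kw.pvalue:.2e}; "
      f"Dunn vs control (Sidak): "
      + ", ".join(f"group {i}: p = {p:.3g}" for i, p in kw.dunn_p_adjusted.items()))

pi = np.linspace(-0.8, 0.8, 9)
cp = 0.5 + 0.45 * pi + rng.normal(0, 0.03, 9)
corr = rank_correlation(pi, cp)
print(f"PI vs choice probability: Spearman rho = {corr.spearman_rho:.2f}, "
      f"Pearson r = {corr.pearson_r:.2f}, R^2 = {corr.r_squared:.2f}")
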