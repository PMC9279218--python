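"""Method-agreement statistics for size measurements.

Simulates per-case tumour volumes measured by a reference method and two
candidates — one unbiased, one that underestimates size-dependently —
and summarises agreement the way measurement-comparison studies do.
"""

import numpy as np

from fractalct import bland_altman, inter_reader_agreement, rank_tests, variance_f_test

rng = np.random.default_rng(7)
n = 24
reference = rng.uniform(5, 60, n)  # mL
good = reference + rng.normal(0, 1.5, n)  # small random error
biased = 0.6 * reference + rng.normal(0, 1.5, n)  # size-dependent underestimation

for name, candidate in (("unbiased method", good), ("underestimating method", biased)):
    ba = bland_altman(reference, candidate)
    print(f"{name}:")
    print(f"  mean difference (ref − test): {ba.mean_diff:+.2f} mL "
          f"[{ba.lower_limit:+.2f}, {ba.upper_limit:+.2f}]")
    print(f"  proportional bias slope: {ba.proportional.slope:+.3f} "
          f"(CI {ba.proportional.slope_ci[0]:+.3f} to {ba.proportional.slope_ci[1]:+.3f})")
    print(f"  correlation: slope {ba.correlation.slope:.3f}, R² {ba.correlation.r2:.3f}")

f_rep = variance_f_test(reference - good, reference - biased)
print(f"\nF-test of difference variances: F = {f_rep.statistic:.2f}, p = {f_rep.p_raw:.3f}")

reports = rank_tests({"reference": reference, "biased": biased}, paired=True)
print(f"paired signed-rank reference vs biased: p = {reports[-1].p_raw:.2e}")

reader2 = good * rng.uniform(0.93, 1.07, n)
agg = inter_reader_agreement(good, reader2)
print(f"\ninter-reader: median discrepancy {agg.median_discrepancy_pct:.1f} % "
      f"(IQR {agg.iqr_pct[0]:.1f}–{agg.iqr_pct[1]:.1f} %), Spearman ρ = {agg.spearman_rho:.3f}")
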