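"""Estimate a mutation rate from a simulated fluctuation assay.

96 parallel cultures grow from 1,000 to ~16.4 million cells with a
per-division reporter-inactivation rate of 6.1e-8 (so m_true ~ 1 mutation
event per culture); the Lea-Coulson MLE recovers m, and dividing by the
colony-count estimate of cells per culture gives the rate.
"""

from mutspec import estimate_m, estimate_nt, mutation_rate
from mutspec.simulate import simulate_fluctuation

n0, nt = 1000, 1000 * 2 ** 14
rate_true = 1.0 / (nt - n0)

experiment, truth = simulate_fluctuation(rate_true, n0, nt, n_cultures=96, seed=42)
print(f"true m = {truth.m_true:.3f}; "
      f"counts: min={min(experiment.mutant_counts)}, "
      f"max={max(experiment.mutant_counts)} (jackpots inflate the max)")

m_hat, lo, hi = estimate_m(experiment)
nt_est = estimate_nt(colony_count=819, dilution_factor=20_000)  # ~nt cells
est = mutation_rate(m_hat, nt_est.nt, ci=(lo, hi))

print(f"m_hat = {m_hat:.3f}  (95% profile CI {lo:.3f}-{hi:.3f})")
print(f"Nt    = {nt_est.nt:.3g} cells per culture")
print(f"rate  = {est.rate:.3g} per reporter gene per division "
      f"(CI {est.ci_low:.2g}-{est.ci_high:.2g})")
print("The rate is m/Nt: mutation events per culture over cells at plating.")
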