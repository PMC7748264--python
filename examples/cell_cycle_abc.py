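"""Infer cell-cycle kinetics from double-labeling fractions with ABC.

The nonspatial division model has five parameters: lag-exponential cell
cycle (delay d_cc, scale beta_cc) and S-phase (d_sp, beta_sp) lengths and
a redivision probability p_rediv. Sequential ABC matches simulated
double-labeled S-phase (DLS) and redivision fractions against the
packaged per-hemisphere count table across labeling intervals 9-72 h.
"""

import numpy as np

from nscpatterns import abc_fit, observed_fraction_table, read_s1_counts

obs = observed_fraction_table(read_s1_counts())
print("observed mean fractions by labeling interval:")
for dt in sorted(obs):
    print(
        f"  dt={dt:4.0f} h  redivision {np.mean(obs[dt]['rediv']):.3f}"
        f"  DLS {np.mean(obs[dt]['dls']):.3f}"
    )

res = abc_fit(obs, epochs=15, particles=100, seed=7, n_cells=10000)
pe = res.point_estimate
print("\nposterior point estimate (weighted median):")
print(f"  minimal cell cycle  d_cc    = {pe.d_cc:5.1f} h")
print(f"  mean cell cycle     d+beta  = {pe.mean_cycle:5.1f} h")
print(f"  minimal S-phase     d_sp    = {pe.d_sp:5.1f} h")
print(f"  mean S-phase        d+beta  = {pe.mean_s_phase:5.1f} h")
print(f"  redivision prob.    p_rediv = {pe.p_rediv:5.2f}")
lo, hi = res.credible_interval("p_rediv", 0.90)
print(f"  p_rediv 90% interval        = [{lo:.2f}, {hi:.2f}]")
print(
    "\nThe DLS decay pins the S-phase length; the redivision plateau at"
    "\nlong intervals constrains p_rediv jointly with the cycle spread."
)
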