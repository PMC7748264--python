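"""Grow an NSC colony with redividing cells and measure it virtually.

A centroid-based agent simulation grows a sheet of soft-disc cells from
500 to ~2,356 cells with spontaneous cycle entries (9e-4 per hour) and
redivisions (one daughter re-enters immediately with probability 0.38).
A virtual double-labeling measurement 48 h apart feeds the discrete
Ripley's K pipeline, exactly as for experimental coordinate tables.
"""

import numpy as np

from nscpatterns import REDIVISION_CONFIG, distance_matrix
from nscpatterns.agents import measurement_readout, simulate_population, virtual_measurement
from nscpatterns.division import FITTED_KINETICS
from nscpatterns.spatial import analyze_pattern

traj = simulate_population(REDIVISION_CONFIG, FITTED_KINETICS, seed=11)
print(
    f"colony grown to {traj.n_alive} cells in {traj.t_final:.0f} h "
    f"({traj.n_completed_divisions} divisions)"
)
print(
    f"divisions followed by an immediate daughter re-entry: "
    f"{100 * traj.redivision_fraction():.1f}% (p_rediv = 38%)"
)

pattern = virtual_measurement(traj, delta_t=48.0, seed=12)
readout = measurement_readout(traj, 48.0, seed=12)
print(
    f"\nvirtual measurement (dt = 48 h): {len(pattern.s1_indices)} Time-1 and "
    f"{len(pattern.s2_indices)} Time-2 S-phase NSCs"
)
print(
    f"snapshot-detected redivisions: {readout.n_rediv} "
    f"({100 * readout.rediv_fraction:.1f}% of Time-1 labels)"
)

d = distance_matrix(pattern.hemisphere)
curve = analyze_pattern(pattern, d, mode="spatiotemporal", seed=13)
window = (curve.radii >= 30) & (curve.radii <= 150)
print(
    f"spatiotemporal pattern: mean z {curve.z_scores[window].mean():+.2f} "
    f"-> {curve.classification}"
)
print(
    "\nRedivisions place a Time-2 S-phase next to its Time-1 mother, the"
    "\nmechanistic seed of spatiotemporal aggregation; snapshot labeling"
    "\nonly catches the subset whose second S-phase spans the measurement."
)
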