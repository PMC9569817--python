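"""Trajectory analytics: RMSF, portal openness, correlated-motion clusters.

Builds two synthetic C-alpha trajectories: one with three planted co-moving
residue blocks (recovered by windowed distance clustering) and one that
toggles between closed and open portal conformations (visible as a bimodal
D-E strand distance).
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from relaxkit.simulate import gen_portal_trajectory, gen_trajectory
from relaxkit.trajectory import correlated_clusters, de_distance_series, rmsf

# --- correlated blocks ------------------------------------------------------
traj, planted = gen_trajectory(
    n_residues=30, n_frames=12000, jitter=0.3, seed=2
)
profile = rmsf(traj)
print(f"mean RMSF: {np.mean(profile.as_array()):.2f} A "
      f"({profile.burn_in_frames} burn-in frames excluded)")

assignment = correlated_clusters(traj, k=3, seed=2)
ari = adjusted_rand_score(planted, assignment.as_array())
print(f"3-block clustering vs planted labels: ARI = {ari:.2f}")
labels = assignment.as_array()
print("cluster sizes:", [int(np.sum(labels == c)) for c in (1, 2, 3)])

# --- portal openness --------------------------------------------------------
portal, state = gen_portal_trajectory(
    closed_distance=7.5, open_distance=10.0, n_frames=3000, seed=2
)
series = de_distance_series(portal)
print(f"\nD-E distance, closed frames: {series[state == 0].mean():.2f} A")
print(f"D-E distance, open frames:   {series[state == 1].mean():.2f} A")
print(f"open-state occupancy: {state.mean():.0%}")
print(
    "\nAn ARI of 1.0 means the windowed distance clustering found exactly the\n"
    "planted co-moving blocks; the two D-E distance modes are the closed and\n"
    "open conformations of the ligand-entry portal."
)
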