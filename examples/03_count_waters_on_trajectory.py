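"""Count first-shell waters per residue along an evaporating trajectory.

Generates a toy annealing trajectory (fixed residue sites, waters escaping
as the ramp passes each residue's retention temperature), counts waters
within the 0.315 nm first-shell cutoff frame by frame, and shows that the
geometric count reproduces the generator's own survival ledger.
"""

import numpy as np

from parchscale import CountParams, SyntheticScenario, count_waters_trajectory
from parchscale.synthetic import generate_toy_trajectory
from parchscale.system_builder import AnnealingSchedule

scn = SyntheticScenario(
    n_residues=3,
    retention_temps_K=np.array([400.0, 550.0, 700.0]),
    n_waters_per_residue=10,
    schedule=AnnealingSchedule(sample_interval_ps=100.0),
    seed=7,
)
params = CountParams(d_water=0.315, use_pbc=False)
toy = generate_toy_trajectory(scn, count_params=params)
series = count_waters_trajectory(toy.structure, toy.frames, params, scn.schedule)

print(f"{series.n_residues} residues x {series.n_frames} frames")
print("temperature/K :", "  ".join(f"{t:5.0f}" for t in series.temperatures_K[::10]))
for label, row in zip(series.residue_labels, series.counts):
    print(f"{label:>9} w(t):", "  ".join(f"{c:5d}" for c in row[::10]))

match = np.array_equal(series.counts, toy.occupancy)
print("counter reproduces the generator's survival ledger exactly:", match)
# Counts drop to zero roughly where the ramp crosses each residue's
# retention temperature (400, 550, 700 K) -- water is lost earliest from
# the residue with the weakest effective water binding.
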