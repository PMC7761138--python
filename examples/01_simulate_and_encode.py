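"""Generate a synthetic dataset and encode its lysines as feature vectors.

Each candidate lysine becomes a 13-residue window (6 on each side, mirror-
padded at the termini) flattened to 104 numbers: 8 structural channels
(ASA, helix/strand/coil probabilities, four backbone angles) per slot.
"""

import numpy as np

from pupstruct import SimConfig, build_dataset, simulate

sim = simulate(SimConfig(n_proteins=20, positive_fraction=0.25, seed=7))
dataset = build_dataset(sim.records, sim.profiles, sim.labels)

print(f"proteins:        {len(sim.records)}")
print(f"lysine sites:    {len(dataset)}  ({dataset.n_pos} pupylated, {dataset.n_neg} not)")
print(f"feature matrix:  {dataset.X.shape}  (sites x window-slots*channels)")
print(f"first features:  {dataset.feature_names[:3]} ... {dataset.feature_names[-1]}")
v = dataset.X[0]
print(f"site {dataset.protein_ids[0]}:{dataset.positions[0]} "
      f"central-slot ASA = {v[6 * 8]:.1f} A^2")
# Each row is one lysine; columns run slot -6..+6, channels asa,ph,pe,pc,
# phi,psi,theta,tau within each slot. These vectors feed cleaning/training.
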