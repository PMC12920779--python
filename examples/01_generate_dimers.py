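"""Generate a charged-dimer dataset with an extrapolation split.

Two rigid 5-atom fragments carrying net charges +1 e and −1 e are placed at
random orientations and separations between 4 and 15 Å. Frames with
separation ≤ 9 Å form the training set; the rest are the extrapolation test
set — beyond anything a 5 Å-cutoff message-passing model can see directly.
"""

import numpy as np

from rangeff import COULOMB_CONSTANT, gen_dimer_dataset, write_extxyz
from rangeff.synthetic_data import default_fragments, interaction_energy, write_split_files

frames, train_idx, test_idx = gen_dimer_dataset(200, seed=0, class_label="CC")
write_extxyz("dimers_cc.xyz", [f.config for f in frames])
write_split_files("dimers_cc.xyz", train_idx, test_idx)

seps = np.array([f.separation for f in frames])
energies = np.array([f.config.energy for f in frames])
print(f"{len(frames)} frames: {len(train_idx)} train (sep ≤ 9 Å), "
      f"{len(test_idx)} extrapolation test (sep > 9 Å)")
print(f"separations {seps.min():.2f}–{seps.max():.2f} Å, "
      f"energies {energies.min():.1f}–{energies.max():.1f} kcal/mol")

# The interaction energy at large separation is the analytic Coulomb tail:
lib = default_fragments()
far = frames[int(test_idx[np.argmax(seps[test_idx])])]
e_int = interaction_energy(far, lib["C+"], lib["C-"])
print(f"frame at {far.separation:.2f} Å: interaction energy {e_int:.3f} kcal/mol, "
      f"point-charge tail −k_e/r = {-COULOMB_CONSTANT / far.separation:.3f} kcal/mol")
print("(the difference is the fragments' higher multipoles plus thermal jitter)")
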