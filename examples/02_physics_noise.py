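"""Corrupt a conformer the way the pretraining task does.

The coordinates are pushed along the Lennard-Jones energy gradient (the
direction interatomic forces act in), and a random subset of atom types is
masked.  The displacement budget of the gradient term is exactly eta.
"""

import numpy as np

from pairbind.physics import LJParams, corrupt, fd_potential_gradient
from pairbind.synthetic import SyntheticSpec, generate_conformer

mol = generate_conformer(SyntheticSpec(seed=0), seed=7)
params = LJParams()

grad = fd_potential_gradient(mol.coords, mol.atom_types, params)
print(f"molecule: {mol.n_atoms} atoms")
print(f"LJ gradient norm: {np.linalg.norm(grad):.3f} kcal/mol/A; "
      f"net force residual {np.abs(grad.sum(axis=0)).max():.2e} "
      f"(internal forces cancel)")

sample = corrupt(mol, seed=123)
disp = np.linalg.norm(sample.noisy_coords - sample.clean_coords, axis=1)
print(f"eta drawn: {sample.noise_meta['eta']:.3f} A; "
      f"per-atom displacement {disp.mean():.3f} +/- {disp.std():.3f} A")
print(f"masked atoms: {sorted(int(i) for i in sample.mask_indices)} "
      f"of {mol.n_atoms} ({len(sample.mask_indices)/mol.n_atoms:.0%})")
print("targets kept for the three heads: clean types, clean distance "
      "matrix, clean coordinates")
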