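"""Per-residue RMSF of a flexible loop on a rigid scaffold.

Builds an ensemble whose first residues are nearly static while the rest
hop between two conformations, then measures per-residue Cα fluctuation
about the iteratively refined mean structure, superposing on the static
part only (so the profile reports loop motion relative to the body).
"""

import numpy as np

from loopscape import ensemble_metrics as em
from loopscape.structure_io import AtomRecord, ConformationEnsemble

rng = np.random.default_rng(0)
n_res = 12
base = rng.normal(0, 4, (n_res, 3))
shifted = base.copy()
shifted[6:] += np.array([3.0, 0.0, 0.0])  # residues 7-12 swing by 3 Å

frames = np.stack([base, shifted] * 50) + rng.normal(0, 0.1, (100, n_res, 3))
atoms = [AtomRecord("A", i + 1, "ALA", "CA", "C") for i in range(n_res)]
ens = ConformationEnsemble(frames, atoms, frame_interval_ps=500.0)

profile = em.rmsf_per_residue(ens, fit_selection=np.arange(6))
print(profile.round(2).to_string(index=False))
print("\nResidues 1-6 fluctuate only by the 0.1 Å jitter; residues 7-12 "
      "add the two-state 3 Å swing (RMSF ~ half the swing amplitude plus "
      "jitter). Fitting on the static half keeps the contrast sharp.")
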