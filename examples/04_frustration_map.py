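"""Local energetic frustration of a salt bridge in a neutral chain.

Places a Glu-Lys contact inside an otherwise glycine chain and computes the
mutational frustration index with exhaustive decoy enumeration: the native
electrostatic attraction beats typical composition-shuffled decoys, so the
contact comes out minimally frustrated.
"""

import numpy as np

from loopscape import frustration as fru
from loopscape.structure_io import AtomRecord, ConformationEnsemble

names = ["GLY", "GLU", "GLY", "GLY", "LYS", "GLY"]
pos = [(0, 0, 0), (4, 0, 0), (8, 0, 0), (0, 4, 0), (4, 4, 0), (8, 4, 0)]
atoms, coords = [], []
for k, (n, p) in enumerate(zip(names, pos), start=1):
    atoms.append(AtomRecord("A", k, n, "CA", "C"))
    coords.append(p)
    if n != "GLY":  # side-chain interaction centre
        atoms.append(AtomRecord("A", k, n, "CB", "C"))
        coords.append(np.add(p, (0.0, 0.0, 1.5)))
ens = ConformationEnsemble(np.array(coords, float)[None], atoms)

fmap = fru.frustration_index(ens, n_decoys=None)  # exhaustive decoys
cols = ["res_i", "name_i", "res_j", "name_j", "r_ij", "f_index",
        "frustration_class"]
print(fmap[cols].round(3).to_string(index=False))
print("\nF is the z-score of the native contact energy against the decoy "
      "distribution (electrostatic strength constant k = 4.15): F >= 0.78 "
      "is minimally frustrated, F <= -1.0 highly frustrated. The Glu2-Lys5 "
      "pair stands out as the only minimally frustrated contact.")
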