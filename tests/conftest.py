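import numpy as np
import pytest

from loopscape.structure_io import AtomRecord, ConformationEnsemble


def make_peptide_ensemble(n_res=5, n_frames=3, seed=0, jitter=0.0,
                          chain="A", first_res=1):
    """Tiny backbone-only ensemble with deterministic or jittered frames."""
    from loopscape.synthetic import build_backbone, backbone_atom_records, helix_template

    rng = np.random.default_rng(seed)
    base = build_backbone(np.array(helix_template(n_res)))
    coords = np.stack([
        base + (rng.normal(0, jitter, base.shape) if jitter else 0.0)
        for _ in range(n_frames)
    ])
    atoms = backbone_atom_records(n_res, chain=chain, first_res=first_res)
    return ConformationEnsemble(coords=coords, atoms=atoms, source_id="toy")


def ca_only_ensemble(positions, res_names=None, chain="A"):
    """Ensemble from explicit per-frame Cα positions: (F, n_res, 3)."""
    positions = np.asarray(positions, dtype=float)
    f, n, _ = positions.shape
    res_names = res_names or ["ALA"] * n
    atoms = [AtomRecord(chain, i + 1, res_names[i], "CA", "C") for i in range(n)]
    return ConformationEnsemble(coords=positions, atoms=atoms, source_id="ca-toy")


@pytest.fixture
def peptide_ensemble():
    return make_peptide_ensemble()


def random_rigid_motion(rng):
    """A random proper rotation and translation."""
    from scipy.spatial.transform import Rotation

    r = Rotation.random(rng=np.random.RandomState(rng.integers(2**31)))
    t = rng.normal(0, 5.0, 3)
    return r.as_matrix(), t
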