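import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from loopscape import synthetic as syn
from loopscape.ensemble_metrics import (
    backbone_dihedrals,
    block_average,
    circular_mean_deg,
    kabsch_superpose,
    rmsd_series,
    rmsf_per_residue,
)
from loopscape.structure_io import ConformationEnsemble

from conftest import make_peptide_ensemble


def _scipy_rmsd_oracle(mobile, reference):
    """Independent optimal-superposition RMSD via scipy's align_vectors."""
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - cr, mobile - cm)
    return rssd / np.sqrt(mobile.shape[0])


class TestKabsch:
    def test_rigidly_moved_copy_has_zero_rmsd(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(0, 3, (20, 3))
        rot = Rotation.random(rng=np.random.RandomState(1)).as_matrix()
        mobile = ref @ rot.T + np.array([5.0, -2.0, 1.0])
        moved, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd < 1e-10
        np.testing.assert_allclose(moved, ref, atol=1e-9)

    def test_single_displaced_atom_rmsd_bounded_and_matches_oracle(self):
        rng = np.random.default_rng(2)
        n = 30
        ref = rng.normal(0, 3, (n, 3))
        mobile = ref.copy()
        mobile[0, 0] += 1.0
        _, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd <= 1.0 / np.sqrt(n) + 1e-12
        assert rmsd == pytest.approx(_scipy_rmsd_oracle(mobile, ref), abs=1e-9)

    def test_reflected_copy_rotation_stays_proper(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 3, (15, 3))
        mobile = ref * np.array([-1.0, 1.0, 1.0])  # improper image
        from loopscape.ensemble_metrics import kabsch_rotation

        r, _, _ = kabsch_rotation(mobile, ref)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
        _, rmsd = kabsch_superpose(mobile, ref)
        assert rmsd > 0.1
        assert rmsd == pytest.approx(_scipy_rmsd_oracle(mobile, ref), abs=1e-9)

    def test_superposed_rmsd_never_exceeds_raw_rmsd(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            ref = rng.normal(0, 2, (12, 3))
            mobile = ref + rng.normal(0, 1.0, ref.shape)
            _, fitted = kabsch_superpose(mobile, ref)
            raw = np.sqrt(np.mean(np.sum((mobile - ref) ** 2, axis=1)))
            assert fitted <= raw + 1e-12

    def test_too_few_or_collinear_fit_atoms_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line + 0.1, line)
        with pytest.raises(ValueError, match="3 fit atoms"):
            kabsch_superpose(line[:2], line[:2])


class TestRmsdSeries:
    def test_identical_frames_give_zero_series(self):
        ens = make_peptide_ensemble(n_res=4, n_frames=6)
        out = rmsd_series(ens)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_two_frame_hand_calculation(self):
        # frame 1 = frame 0 with every atom shifted 1 Å along x: the optimal
        # superposition removes the shift entirely, RMSD = 0; without
        # superposition it would be 1. A non-uniform stretch survives.
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        stretched = base * np.array([1.5, 1.0, 1.0])
        from loopscape.structure_io import AtomRecord

        ens = ConformationEnsemble(
            np.stack([base, stretched]),
            atoms=[AtomRecord("A", i + 1, "GLY", "CA") for i in range(4)],
        )
        out = rmsd_series(ens)
        assert out.values[0] == pytest.approx(0.0, abs=1e-12)
        assert out.values[1] == pytest.approx(
            _scipy_rmsd_oracle(stretched, base), abs=1e-9)

    def test_expected_rmsd_grows_with_jitter(self):
        means = []
        for sigma in (0.1, 0.3, 0.6):
            ens = make_peptide_ensemble(n_res=6, n_frames=50, jitter=sigma, seed=8)
            means.append(rmsd_series(ens).values[1:].mean())
        assert means[0] < means[1] < means[2]

    def test_bad_reference_frame_rejected(self):
        ens = make_peptide_ensemble(n_frames=3)
        with pytest.raises(IndexError):
            rmsd_series(ens, reference_frame=7)


class TestRmsf:
    def test_identical_frames_are_exactly_zero(self):
        ens = make_peptide_ensemble(n_res=5, n_frames=4)
        out = rmsf_per_residue(ens)
        np.testing.assert_allclose(out["rmsf_ang"], 0.0, atol=1e-12)

    def test_single_frame_rejected(self):
        ens = make_peptide_ensemble(n_frames=1)
        with pytest.raises(ValueError):
            rmsf_per_residue(ens)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self):
        # RMSF of i.i.d. Gaussian jitter sigma per coordinate is sigma*sqrt(3);
        # superposition onto the mean shrinks it slightly (6 fitted dof over
        # 3*A coordinates), well inside the 5% tolerance at this size.
        sigma = 0.25
        ens = make_peptide_ensemble(n_res=18, n_frames=4000, jitter=sigma, seed=12)
        out = rmsf_per_residue(ens)
        mean_rmsf = out["rmsf_ang"].mean()
        assert mean_rmsf == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_mobile_loop_exceeds_static_scaffold(self):
        # residues 1-4 static, residues 5-8 alternate between two positions
        rng = np.random.default_rng(5)
        base = rng.normal(0, 3, (8, 3))
        shifted = base.copy()
        shifted[4:] += np.array([3.0, 0, 0])
        frames = np.stack([base, shifted] * 20)
        frames += rng.normal(0, 0.05, frames.shape)
        from conftest import ca_only_ensemble

        ens = ca_only_ensemble(frames)
        fit_idx = np.arange(4)  # superpose on the static scaffold
        out = rmsf_per_residue(ens, fit_selection=fit_idx)
        scaffold = out["rmsf_ang"][:4].mean()
        loop = out["rmsf_ang"][4:].mean()
        assert loop > 5 * scaffold

    def test_invariant_to_global_rigid_motion_per_frame(self):
        # pose noise on vs off: RMSF relative to the refined mean must agree
        spec_kwargs = dict(n_res=6, n_frames=300, seed=21)
        basins = (syn.BasinSpec(syn.helix_template(6), 0.2, 1.0),)
        still = syn.EnsembleSpec(basins=basins, **spec_kwargs)
        tumbling = syn.EnsembleSpec(basins=basins, pose_rotation_deg=20.0,
                                    pose_translation_ang=3.0, **spec_kwargs)
        e1, _ = syn.sample_ensemble(still)
        e2, _ = syn.sample_ensemble(tumbling)
        r1 = rmsf_per_residue(e1)["rmsf_ang"]
        r2 = rmsf_per_residue(e2)["rmsf_ang"]
        # same jitter process; superposition removes the pose noise
        np.testing.assert_allclose(r1, r2, rtol=0.15)


class TestDihedrals:
    def test_two_residue_chain_has_one_phi_one_psi(self):
        ens = make_peptide_ensemble(n_res=2, n_frames=1)
        d = backbone_dihedrals(ens)
        assert np.isnan(d["phi"][0, 0]) and not np.isnan(d["phi"][0, 1])
        assert not np.isnan(d["psi"][0, 0]) and np.isnan(d["psi"][0, 1])

    def test_angles_in_half_open_interval(self):
        ens = make_peptide_ensemble(n_res=8, n_frames=5, jitter=0.4, seed=3)
        d = backbone_dihedrals(ens)
        for key in ("phi", "psi", "omega"):
            vals = d[key][~np.isnan(d[key])]
            assert np.all(vals > -180.0) and np.all(vals <= 180.0)

    def test_missing_backbone_atom_yields_nan_with_warning(self):
        ens = make_peptide_ensemble(n_res=3, n_frames=1)
        # drop residue 2's C atom
        keep = [i for i, a in enumerate(ens.atoms)
                if not (a.res_seq == 2 and a.atom_name == "C")]
        sub = ConformationEnsemble(ens.coords[:, keep, :],
                                   [ens.atoms[i] for i in keep])
        with pytest.warns(UserWarning, match="missing backbone"):
            d = backbone_dihedrals(sub)
        assert np.isnan(d["phi"][0, 1])


class TestBlocks:
    def test_block_means_and_partial_flag(self):
        out = block_average(np.arange(10.0), 4)
        np.testing.assert_allclose(out.block_means, [1.5, 5.5, 8.5])
        assert out.last_partial

    def test_exact_division_has_no_partial(self):
        out = block_average(np.arange(8.0), 4)
        assert not out.last_partial
        assert len(out.block_means) == 2

    def test_circular_mean_handles_wraparound(self):
        vals = np.array([179.0, -179.0])
        assert abs(circular_mean_deg(vals)) == pytest.approx(180.0, abs=1e-9)
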