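import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from loopscape import loop_clustering as lc
from loopscape import synthetic as syn
from loopscape.cli import default_basin_spec

from conftest import make_peptide_ensemble


def _three_basin_ensemble(seed, n_frames=500, n_res=8, jitter=0.15):
    spec = default_basin_spec(n_res=n_res, n_basins=3, frames=n_frames,
                              jitter=jitter, stay_prob=0.9, seed=seed)
    return syn.sample_ensemble(spec)


class TestLoopMatrix:
    def test_18_residue_loop_gives_72_atoms_216_columns(self):
        ens = make_peptide_ensemble(n_res=18, n_frames=5, first_res=342)
        m, src = lc.loop_matrix([ens], "A", (342, 359), align="loop")
        assert m.shape == (5, 216)

    def test_three_sources_concatenate_in_order(self):
        ensembles = []
        for k in range(3):
            e, _ = _three_basin_ensemble(seed=k, n_frames=100)
            e.source_id = f"sys{k}"
            ensembles.append(e)
        m, src = lc.loop_matrix(ensembles, "A", (1, 8), align="loop")
        assert m.shape[0] == 300
        assert list(np.unique(src, return_counts=True)[1]) == [100, 100, 100]
        assert list(src[:100]) == ["sys0"] * 100

    def test_single_frame_matrix(self):
        ens = make_peptide_ensemble(n_res=18, n_frames=1, first_res=342)
        m, _ = lc.loop_matrix([ens], "A", (342, 359), align="none")
        assert m.shape == (1, 216)

    def test_layout_mismatch_names_source(self):
        a = make_peptide_ensemble(n_res=6)
        b = make_peptide_ensemble(n_res=5)
        b.source_id = "short-loop"
        with pytest.raises(ValueError, match="short-loop"):
            lc.loop_matrix([a, b], "A", (1, 6), align="loop")


class TestPCA:
    def test_exact_line_concentrates_variance_on_first_pc(self):
        t = np.linspace(-1, 1, 50)[:, None]
        direction = np.array([[1.0, 2.0, -0.5, 3.0]])
        m = t @ direction
        model = lc.fit_pca(m)
        assert model.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(model.variance_fraction[1:], 0.0, atol=1e-12)

    def test_components_orthonormal_and_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, (200, 12))
        model = lc.fit_pca(m)
        np.testing.assert_allclose(model.components @ model.components.T,
                                   np.eye(12), atol=1e-8)
        assert model.variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_isotropic_cloud_has_flat_spectrum(self):
        rng = np.random.default_rng(1)
        d = 6
        m = rng.normal(0, 1, (10_000, d))
        model = lc.fit_pca(m)
        np.testing.assert_allclose(model.variance_fraction, 1.0 / d, rtol=0.06)

    def test_full_reconstruction_is_lossless(self):
        rng = np.random.default_rng(2)
        m = rng.normal(0, 2, (40, 9))
        model = lc.fit_pca(m)
        proj = model.project(m)
        np.testing.assert_allclose(model.reconstruct(proj), m, atol=1e-6)

    def test_rank_deficient_directions_report_zero_eigenvalue(self):
        rng = np.random.default_rng(3)
        m = rng.normal(0, 1, (5, 10))  # rank <= 4 after centering
        model = lc.fit_pca(m)
        assert np.all(model.eigenvalues[4:] < 1e-10)

    def test_fewer_than_two_frames_rejected(self):
        with pytest.raises(ValueError):
            lc.fit_pca(np.zeros((1, 6)))


class TestMinClusterSize:
    @pytest.mark.parametrize("n,frac,expected", [
        (8993, 0.01, 90),   # round-half-up of 89.93
        (100, 0.01, 2),     # floor guard
        (200, 0.01, 2),     # round(2.0) = 2
        (250, 0.01, 3),     # 2.5 rounds half-up
        (1, 0.01, 2),
    ])
    def test_rounding_rule(self, n, frac, expected):
        assert lc.min_cluster_size(n, frac) == expected

    def test_nonpositive_fraction_rejected(self):
        with pytest.raises(ValueError):
            lc.min_cluster_size(100, 0.0)


class TestClustering:
    def test_three_basin_recovery_across_seeds(self):
        # well-separated basins (template separation >> jitter): the density
        # clustering must recover the generator's labels almost perfectly.
        # Clustered in the full PC space (the default, distance-preserving)
        # with the minimum cluster size at basin scale (5% of frames).
        aris = []
        for seed in range(10):
            ens, truth = _three_basin_ensemble(seed)
            m, _ = lc.loop_matrix([ens], "A", (1, 8), align="loop")
            model = lc.fit_pca(m)
            proj = model.project(m)
            a = lc.cluster_conformations(
                proj, lc.min_cluster_size(len(truth), 0.05))
            aris.append(adjusted_rand_score(truth, a.labels))
        assert np.mean(aris) >= 0.95

    def test_single_blob_is_one_cluster(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.1, (300, 2))
        a = lc.cluster_conformations(x, 10)
        assert a.n_clusters == 1  # noise points allowed, but one cluster only

    def test_fewer_frames_than_min_size_all_noise_with_warning(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (5, 2))
        with pytest.warns(UserWarning, match="noise"):
            a = lc.cluster_conformations(x, 10)
        assert a.n_clusters == 0
        assert np.all(a.labels == -1)

    def test_sparse_uniform_noise_yields_no_cluster(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1000, (60, 2))  # density far below min size 30
        a = lc.cluster_conformations(x, 30)
        assert a.n_clusters <= 1
        assert np.sum(a.labels == -1) >= 30

    def test_clusters_labelled_by_descending_size(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(0, 0.05, (150, 2)),
                       rng.normal(10, 0.05, (50, 2))])
        a = lc.cluster_conformations(x, 10)
        assert a.n_clusters == 2
        assert a.sizes[0] >= a.sizes[1]
        assert np.sum(a.labels == 0) == a.sizes[0]

    def test_full_pc_space_equals_raw_space_clustering(self):
        # Euclidean HDBSCAN is rotation invariant: clustering in the full
        # PC projection must give the same partition as the centred matrix
        ens, _ = _three_basin_ensemble(seed=3, n_frames=300)
        m, _ = lc.loop_matrix([ens], "A", (1, 8), align="loop")
        model = lc.fit_pca(m)
        proj_full = model.project(m)
        centred = m - m.mean(axis=0)
        size = lc.min_cluster_size(m.shape[0])
        a1 = lc.cluster_conformations(proj_full, size)
        a2 = lc.cluster_conformations(centred, size)
        assert adjusted_rand_score(a1.labels, a2.labels) == pytest.approx(1.0)

    def test_partition_stable_under_row_shuffling(self):
        ens, _ = _three_basin_ensemble(seed=9, n_frames=300)
        m, _ = lc.loop_matrix([ens], "A", (1, 8), align="loop")
        size = lc.min_cluster_size(m.shape[0])
        a1 = lc.cluster_conformations(m - m.mean(0), size)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.shape[0])
        a2 = lc.cluster_conformations(m[perm] - m.mean(0), size)
        assert adjusted_rand_score(a1.labels[perm], a2.labels) == pytest.approx(1.0)


class TestMedoid:
    def test_collinear_hand_check(self):
        matrix = np.array([[0.0], [1.0], [10.0]])
        a = lc.ClusterAssignment(labels=np.zeros(3, dtype=int), n_clusters=1,
                                 sizes=np.array([3]), min_size=2)
        assert lc.cluster_medoid(a, matrix) == {0: 1}

    def test_symmetric_tie_takes_lower_frame_index(self):
        matrix = np.array([[0.0], [2.0]])
        a = lc.ClusterAssignment(labels=np.zeros(2, dtype=int), n_clusters=1,
                                 sizes=np.array([2]), min_size=2)
        assert lc.cluster_medoid(a, matrix) == {0: 0}

    def test_matches_exhaustive_search_on_random_clusters(self):
        rng = np.random.default_rng(8)
        matrix = rng.normal(0, 1, (200, 4))
        labels = rng.integers(0, 3, 200)
        sizes = np.bincount(labels)
        a = lc.ClusterAssignment(labels=labels, n_clusters=3,
                                 sizes=np.sort(sizes)[::-1], min_size=2)
        medoids = lc.cluster_medoid(a, matrix)
        for cl in range(3):
            idx = np.flatnonzero(labels == cl)
            best, best_total = None, np.inf
            for i in idx:  # brute-force O(n^2) oracle
                total = sum(np.linalg.norm(matrix[i] - matrix[j]) for j in idx)
                if total < best_total - 1e-12:
                    best, best_total = i, total
            assert medoids[cl] == best


class TestOccupancyTable:
    def test_single_source_row_sums_to_frame_count(self):
        ens, truth = _three_basin_ensemble(seed=2, n_frames=300)
        m, src = lc.loop_matrix([ens], "A", (1, 8), align="loop")
        a = lc.cluster_conformations(m - m.mean(0), lc.min_cluster_size(300))
        table = lc.cluster_occupancy_table(a, src)
        count_cols = [c for c in table.columns if not c.endswith("_frac")]
        assert table[count_cols].sum(axis=1).item() == 300

    def test_unvisited_basin_shows_zero_and_shared_basin_overlap(self):
        # source A explores basins 0+1, source B only basin 0: expect one
        # shared cluster (both nonzero) and one exclusive to A
        t0 = syn.helix_template(6, -60, -45)
        t1 = syn.helix_template(6, -120, 130)
        spec_a = syn.EnsembleSpec(
            n_res=6, basins=(syn.BasinSpec(t0, 0.1, 0.5), syn.BasinSpec(t1, 0.1, 0.5)),
            stay_prob=0.8, n_frames=200, seed=1, source_id="A")
        spec_b = syn.EnsembleSpec(
            n_res=6, basins=(syn.BasinSpec(t0, 0.1, 1.0),),
            stay_prob=0.8, n_frames=200, seed=2, source_id="B")
        ea, _ = syn.sample_ensemble(spec_a)
        eb, _ = syn.sample_ensemble(spec_b)
        m, src = lc.loop_matrix([ea, eb], "A", (1, 6), align="loop")
        a = lc.cluster_conformations(m - m.mean(0), lc.min_cluster_size(400))
        table = lc.cluster_occupancy_table(a, src)
        assert a.n_clusters == 2
        shared = [c for c in (f"cluster_{k}" for k in range(2))
                  if (table[c] > 0).all()]
        exclusive = [c for c in (f"cluster_{k}" for k in range(2))
                     if (table.loc["B", c] == 0)]
        assert len(shared) == 1
        assert len(exclusive) == 1
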