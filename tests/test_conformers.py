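import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import oracle_gromos, oracle_min_rmsd, oracle_pairwise_rmsd
from vsbench.conformers import (
    ClusterResult,
    ConformerEnsemble,
    atoms_near,
    gromos_cluster,
    kabsch_superpose,
    read_pdb_frames,
    read_xyz_frames,
    rmsd_matrix,
    select_centroids,
)
from vsbench.synthetic import gen_conformers


def rigid_copy(coords, seed=0, shift=(3.0, -1.0, 7.0)):
    rot = Rotation.random(random_state=seed).as_matrix()
    return coords @ rot.T + np.asarray(shift)


class TestKabsch:
    def test_identical_sets_zero_rmsd_identity_rotation(self, rng):
        pts = rng.normal(0, 2, size=(10, 3))
        r, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd <= 1e-9
        np.testing.assert_allclose(r, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)

    def test_exact_recovery_of_rigid_motion(self, rng):
        pts = rng.normal(0, 2, size=(12, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot90.T + np.array([1.0, 2.0, 3.0])
        _, _, rmsd = kabsch_superpose(pts, moved)
        assert rmsd <= 1e-9

    def test_proper_rotation_even_for_reflected_data(self, rng):
        pts = rng.normal(0, 2, size=(8, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        r, _, _ = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_optimization_oracle(self, rng):
        for seed in range(3):
            local = np.random.default_rng(seed)
            a = local.normal(0, 1.5, size=(4, 3))
            b = local.normal(0, 1.5, size=(4, 3))
            _, _, rmsd = kabsch_superpose(a, b)
            assert rmsd == pytest.approx(oracle_min_rmsd(a, b, seed=seed), abs=1e-6)

    def test_superposed_rmsd_never_exceeds_raw_rmsd(self, rng):
        for _ in range(10):
            a = rng.normal(0, 2, size=(15, 3))
            b = rng.normal(0, 2, size=(15, 3))
            raw = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
            _, _, fitted = kabsch_superpose(a, b)
            assert fitted <= raw + 1e-12

    def test_count_mismatch_and_degenerate_geometry(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 1.0, 0.0]))
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line + 1.0)


class TestRmsdMatrix:
    def test_identical_frames_zero_matrix(self):
        frame = np.random.default_rng(0).normal(0, 2, size=(10, 3))
        ens = ConformerEnsemble(frames=np.stack([frame] * 4))
        np.testing.assert_allclose(rmsd_matrix(ens), 0.0, atol=1e-9)

    def test_rigidly_moved_frame_vanishes_after_superposition(self, rng):
        frame = rng.normal(0, 2, size=(10, 3))
        ens = ConformerEnsemble(frames=np.stack([frame, rigid_copy(frame)]))
        m = rmsd_matrix(ens, superpose_first=True)
        assert m[0, 1] <= 1e-9
        raw = rmsd_matrix(ens, superpose_first=False)
        assert raw[0, 1] > 1.0

    def test_matches_pairwise_brute_force(self, rng):
        frames = rng.normal(0, 1, size=(5, 8, 3))
        ens = ConformerEnsemble(frames=frames)
        got = rmsd_matrix(ens, superpose_first=False)
        np.testing.assert_allclose(got, oracle_pairwise_rmsd(frames), atol=1e-9)
        assert np.allclose(got, got.T)
        assert np.all(np.diag(got) == 0.0)

    def test_mask_subsets_atoms(self, rng):
        frames = rng.normal(0, 1, size=(3, 10, 3))
        ens = ConformerEnsemble(frames=frames)
        sub = rmsd_matrix(ens, mask=[0, 1, 2], superpose_first=False)
        np.testing.assert_allclose(
            sub, oracle_pairwise_rmsd(frames[:, :3, :]), atol=1e-9
        )
        with pytest.raises(ValueError):
            rmsd_matrix(ens, mask=[])


class TestGromosCluster:
    def test_loose_cutoff_single_cluster(self, rng):
        m = oracle_pairwise_rmsd(rng.normal(0, 1, size=(6, 5, 3)))
        res = gromos_cluster(m, cutoff=m.max() + 1.0)
        assert res.sizes() == [6]

    def test_tight_cutoff_all_singletons(self, rng):
        m = oracle_pairwise_rmsd(rng.normal(0, 1, size=(6, 5, 3)))
        off_diag_min = m[m > 0].min()
        res = gromos_cluster(m, cutoff=off_diag_min / 2.0)
        assert res.sizes() == [1] * 6

    def test_planted_three_blob_recovery(self):
        ens, labels = gen_conformers(
            n_frames=30, n_atoms=20, n_blobs=3, separation=6.0, jitter_sd=0.1, seed=8
        )
        res = gromos_cluster(rmsd_matrix(ens), cutoff=1.0)
        assert len(res.clusters) == 3
        got = res.labels(ens.n_frames)
        # same partition as planted labels, up to cluster renaming
        for k in range(3):
            members = np.flatnonzero(got == k)
            assert len(set(labels[members])) == 1
        assert sorted(res.sizes(), reverse=True) == sorted(
            np.bincount(labels).tolist(), reverse=True
        )

    def test_matches_brute_force_oracle(self, rng):
        for seed in range(20):
            local = np.random.default_rng(seed)
            m = oracle_pairwise_rmsd(local.normal(0, 1, size=(10, 4, 3)))
            cutoff = float(np.median(m[m > 0]))
            got = gromos_cluster(m, cutoff)
            want = oracle_gromos(m, cutoff)
            assert [(c, sorted(mem)) for c, mem in got.clusters] == [
                (c, sorted(mem)) for c, mem in want
            ]

    def test_output_is_partition(self, rng):
        m = oracle_pairwise_rmsd(rng.normal(0, 1, size=(12, 4, 3)))
        res = gromos_cluster(m, cutoff=float(np.median(m)))
        all_members = [f for _, members in res.clusters for f in members]
        assert sorted(all_members) == list(range(12))

    def test_validates_input(self, rng):
        m = rng.normal(size=(4, 4))
        with pytest.raises(ValueError, match="symmetric"):
            gromos_cluster(m, 1.0)
        with pytest.raises(ValueError):
            gromos_cluster(np.zeros((3, 3)), 0.0)


class TestSelectCentroids:
    def test_fewer_clusters_than_requested_warns(self):
        res = ClusterResult(clusters=[(0, [0, 1]), (2, [2])], cutoff=1.0)
        with pytest.warns(UserWarning, match="only 2 clusters"):
            picks = select_centroids(res, top_k=5)
        assert picks == [0, 2]

    def test_equal_sizes_earliest_centroid_first(self):
        res = ClusterResult(clusters=[(1, [1, 3]), (5, [5, 6])], cutoff=1.0)
        assert select_centroids(res, top_k=2) == [1, 5]

    def test_extra_frame_appended(self):
        res = ClusterResult(clusters=[(0, [0, 1]), (2, [2])], cutoff=1.0)
        assert select_centroids(res, top_k=2, extra=[7, 0]) == [0, 2, 7]

    def test_planted_centroids_sit_in_their_blobs(self):
        ens, labels = gen_conformers(
            n_frames=40, n_atoms=15, n_blobs=3, separation=6.0, jitter_sd=0.1, seed=2
        )
        res = gromos_cluster(rmsd_matrix(ens), cutoff=1.0)
        picks = select_centroids(res, top_k=3)
        assert len({labels[p] for p in picks}) == 3


class TestPocketMask:
    def test_distance_shell_selection(self):
        frame = np.array(
            [[0, 0, 0], [1, 0, 0], [5, 0, 0], [20, 0, 0.0]]
        )
        idx = atoms_near(frame, pocket_indices=[0], radius=6.0, heavy_only=False)
        assert idx.tolist() == [0, 1, 2]

    def test_hydrogens_excluded(self):
        frame = np.zeros((3, 3))
        idx = atoms_near(frame, [0], radius=5.0, elements=["C", "H", "N"])
        assert idx.tolist() == [0, 2]


class TestReaders:
    def test_multi_model_pdb(self, tmp_path):
        pdb = []
        for model in (1, 2):
            pdb.append(f"MODEL     {model}")
            for k, (x, y, z) in enumerate(
                [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (1.5, 1.5, float(model))]
            ):
                pdb.append(
                    f"ATOM  {k + 1:>5}  CA  ALA A{k + 1:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                )
            pdb.append("ENDMDL")
        pdb.append("END")
        path = tmp_path / "traj.pdb"
        path.write_text("\n".join(pdb) + "\n")
        ens = read_pdb_frames(path)
        assert ens.n_frames == 2 and ens.n_atoms == 3
        assert ens.frames[1, 2, 2] == pytest.approx(2.0)

    def test_xyz_frames(self, tmp_path):
        text = "2\nframe0\nC 0.0 0.0 0.0\nN 1.0 0.0 0.0\n" \
               "2\nframe1\nC 0.0 0.0 0.5\nN 1.0 0.0 0.5\n"
        path = tmp_path / "traj.xyz"
        path.write_text(text)
        ens = read_xyz_frames(path)
        assert ens.n_frames == 2 and ens.n_atoms == 2
        assert ens.elements == ["C", "N"]
        assert ens.frames[1, 0, 2] == pytest.approx(0.5)
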