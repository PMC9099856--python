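"""Binding-space parameterization: retention filter, rmsd, summary,
clustering, orientation classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bindspace.ensemble import (
    LigandPose,
    PoseEnsemble,
    binding_space_summary,
    classify_orientation,
    cluster_poses,
    filter_top_poses,
    pose_rmsd,
)
from bindspace.structures import InputError
from bindspace import synthetic as syn


def _poses_from_dgs(mdma_like, dgs, jitter=None):
    rng = np.random.default_rng(0)
    out = []
    for dg in dgs:
        conf = mdma_like.copy()
        if jitter is not None:
            conf.set_coords(conf.coords + rng.normal(0, jitter, conf.coords.shape))
        out.append(LigandPose(conformer=conf, delta_g=float(dg)))
    return out


class TestRetentionFilter:
    def test_keeps_80_most_favourable_of_200(self, mdma_like):
        rng = np.random.default_rng(1)
        dgs = rng.uniform(-9, -2, 200)
        ens = filter_top_poses(_poses_from_dgs(mdma_like, dgs))
        assert len(ens) == 80
        # oracle: brute-force sort-and-slice
        expected = np.sort(dgs)[:80]
        got = np.array([p.delta_g for p in ens.poses])
        assert np.allclose(got, expected)
        assert np.all(np.diff(got) >= 0)

    def test_fewer_poses_all_kept(self, mdma_like):
        ens = filter_top_poses(_poses_from_dgs(mdma_like, [-5, -7, -6]))
        assert [p.delta_g for p in ens.poses] == [-7, -6, -5]

    def test_idempotent_and_subset(self, mdma_like):
        poses = _poses_from_dgs(mdma_like, np.linspace(-9, -1, 120))
        once = filter_top_poses(poses)
        twice = filter_top_poses(once.poses)
        assert [p.delta_g for p in once.poses] == [p.delta_g for p in twice.poses]
        assert {id(p) for p in once.poses} <= {id(p) for p in poses}

    def test_ties_broken_by_input_order(self, mdma_like):
        poses = _poses_from_dgs(mdma_like, [-5.0, -5.0, -5.0])
        ens = filter_top_poses(poses, max_n=2)
        assert ens.poses[0] is poses[0] and ens.poses[1] is poses[1]

    def test_unscored_pose_rejected(self, mdma_like):
        poses = _poses_from_dgs(mdma_like, [-5.0])
        poses.append(LigandPose(conformer=mdma_like.copy(), delta_g=None))
        with pytest.raises(InputError):
            filter_top_poses(poses)


class TestPoseRmsd:
    def test_identical_zero(self, mdma_like):
        p = LigandPose(mdma_like.copy(), -7.0)
        assert pose_rmsd(p, p) == 0.0

    def test_translation_345(self, mdma_like):
        a = LigandPose(mdma_like.copy(), -7.0)
        b = LigandPose(mdma_like.translated([3.0, 4.0, 0.0]), -7.0)
        assert pose_rmsd(a, b) == pytest.approx(5.0)

    def test_matches_direct_formula(self, mdma_like, rng):
        a = LigandPose(mdma_like.copy(), -7.0)
        conf = mdma_like.copy()
        conf.set_coords(conf.coords + rng.normal(0, 1.0, conf.coords.shape))
        b = LigandPose(conf, -6.0)
        idx = mdma_like.heavy_indices()
        direct = np.sqrt(
            ((a.conformer.coords[idx] - b.conformer.coords[idx]) ** 2).sum() / len(idx)
        )
        assert pose_rmsd(a, b) == pytest.approx(direct, abs=1e-9)

    def test_pseudometric_and_superposition_bound(self, mdma_like, rng):
        a = LigandPose(mdma_like.copy(), -7.0)
        for _ in range(5):
            conf = mdma_like.copy()
            rot = Rotation.random(rng=rng)
            conf.set_coords(rot.apply(conf.coords) + rng.uniform(-3, 3, 3))
            b = LigandPose(conf, -6.0)
            assert pose_rmsd(a, b) == pytest.approx(pose_rmsd(b, a))
            assert pose_rmsd(a, b) >= 0
            assert pose_rmsd(a, b, superpose=True) <= pose_rmsd(a, b) + 1e-9
            # pure rigid motion: superposed rmsd ~ 0
            assert pose_rmsd(a, b, superpose=True) == pytest.approx(0.0, abs=1e-6)

    def test_atom_count_mismatch(self, mdma_like):
        probe = syn.make_toy_ligand("probe_amine")
        with pytest.raises(InputError):
            pose_rmsd(LigandPose(mdma_like, -7.0), LigandPose(probe, -6.0))


class TestSummary:
    def test_arithmetic_on_known_dgs(self, mdma_like):
        ens = PoseEnsemble(_poses_from_dgs(mdma_like, [-5.0, -6.0, -7.0], jitter=0.2))
        s = binding_space_summary(ens)
        assert s.mean_dg == pytest.approx(-6.0)
        assert s.range_dg == pytest.approx(2.0)
        assert s.sd_dg == pytest.approx(1.0)
        assert s.n_poses == 3
        # mode: most populated 0.5 bin anchored at -7 -> first bin, centre -6.75
        ens2 = PoseEnsemble(
            _poses_from_dgs(mdma_like, [-7.0, -6.9, -6.8, -5.0], jitter=0.2)
        )
        assert binding_space_summary(ens2).mode_dg == pytest.approx(-6.75)

    def test_per_state_counts(self, mdma_like):
        poses = _poses_from_dgs(mdma_like, np.linspace(-8, -5, 80), jitter=0.1)
        for i, p in enumerate(poses):
            p.source_state = "A" if i < 30 else "B"
        s = binding_space_summary(PoseEnsemble(poses))
        assert s.per_state_counts == {"A": 30, "B": 50}

    def test_mean_pairwise_rmsd_matches_double_loop(self, mdma_like):
        poses = _poses_from_dgs(mdma_like, [-7, -6.5, -6, -5.5], jitter=0.8)
        ens = PoseEnsemble(poses)
        s = binding_space_summary(ens)
        n = len(poses)
        vals = [
            pose_rmsd(poses[i], poses[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        assert s.mean_pairwise_rmsd == pytest.approx(np.mean(vals))

    def test_single_pose_fields_absent(self, mdma_like):
        s = binding_space_summary(PoseEnsemble(_poses_from_dgs(mdma_like, [-7.0])))
        assert s.sd_dg is None and s.mean_pairwise_rmsd is None

    def test_matches_brute_force_on_planted_ensemble(self, pocket, mdma_like):
        ens = syn.plant_pose_ensemble(
            pocket, mdma_like, syn.EnsembleSpec(n_poses=40, seed=11)
        )
        s = binding_space_summary(ens)
        dgs = np.array([p.delta_g for p in ens.poses])
        assert s.mean_dg == pytest.approx(dgs.mean())
        assert s.sd_dg == pytest.approx(dgs.std(ddof=1))
        assert s.range_dg == pytest.approx(dgs.max() - dgs.min())
        assert sum(s.per_state_counts.values()) == 40


class TestClustering:
    def test_identical_poses_single_cluster(self, mdma_like):
        ens = PoseEnsemble(_poses_from_dgs(mdma_like, [-7, -6, -5]))
        res = cluster_poses(ens)
        assert res.n_clusters == 1
        assert res.representative_index == 0

    def test_two_planted_blobs(self, pocket, mdma_like):
        spec = syn.EnsembleSpec(
            n_poses=30, planted_frequencies=(), cluster_spread=0.5,
            cluster_separation=8.0, torsion_jitter=5.0, rotation_jitter=1.5,
            orientation_mix=(1.0, 0.0, 0.0), seed=3,
        )
        ens = syn.plant_pose_ensemble(pocket, mdma_like, spec)
        res = cluster_poses(ens, threshold=3.0)
        assert res.n_clusters == 2
        assert sorted(np.bincount(res.labels)) == [15, 15]
        # every pose within threshold of its leader
        leaders = {}
        for i, lab in enumerate(res.labels):
            leaders.setdefault(lab, i)
        for i, lab in enumerate(res.labels):
            assert pose_rmsd(ens.poses[leaders[lab]], ens.poses[i]) <= 3.0
        # representative is the medoid of the largest cluster
        top = int(np.bincount(res.labels).argmax())
        members = [i for i, l in enumerate(res.labels) if l == top]
        sums = {
            i: sum(pose_rmsd(ens.poses[i], ens.poses[j]) for j in members if j != i)
            for i in members
        }
        assert sums[res.representative_index] == pytest.approx(min(sums.values()))

    def test_infinite_threshold_single_cluster(self, mdma_like):
        ens = PoseEnsemble(_poses_from_dgs(mdma_like, [-7, -6, -5], jitter=3.0))
        res = cluster_poses(ens, threshold=np.inf)
        assert res.n_clusters == 1


class TestOrientation:
    def _ref(self, mdma_like, axis, rng):
        feats = syn._ligand_feature_points(mdma_like)
        return LigandPose(
            syn._base_pose(mdma_like, feats, np.asarray(axis, float), rng, roll_deg=0.0),
            -7.0,
        )

    def test_aligned_orthogonal_and_thresholds(self, mdma_like, rng):
        ref_a = self._ref(mdma_like, [1, 0, 0], rng)
        ref_b = self._ref(mdma_like, [-1, 0, 0], rng)
        assert classify_orientation(ref_a, ref_a, ref_b).label == "serotonin_like"
        assert classify_orientation(ref_b, ref_a, ref_b).label == "escitalopram_like"
        mid = self._ref(mdma_like, [0, 0, 1], rng)  # 90 deg to both
        assert classify_orientation(mid, ref_a, ref_b).label == "intermediate"

    def test_35_degrees_to_a_80_to_b(self, mdma_like, rng):
        axis_a = np.array([1.0, 0.0, 0.0])
        # rotate ref_b's axis 115 deg from a so that p at 35 deg to a is 80 to b
        axis_b = np.array([np.cos(np.deg2rad(115)), np.sin(np.deg2rad(115)), 0.0])
        axis_p = np.array([np.cos(np.deg2rad(35)), np.sin(np.deg2rad(35)), 0.0])
        ref_a = self._ref(mdma_like, axis_a, rng)
        ref_b = self._ref(mdma_like, axis_b, rng)
        p = self._ref(mdma_like, axis_p, rng)
        lab = classify_orientation(p, ref_a, ref_b)
        assert lab.label == "serotonin_like"
        assert lab.angle_to_refs["serotonin_like"] == pytest.approx(35.0, abs=1.0)
        assert lab.angle_to_refs["escitalopram_like"] == pytest.approx(80.0, abs=1.0)

    def test_invariant_under_joint_rigid_rotation(self, mdma_like, rng):
        ref_a = self._ref(mdma_like, [1, 0, 0], rng)
        ref_b = self._ref(mdma_like, [-1, 0, 0], rng)
        p = self._ref(mdma_like, [np.cos(0.3), np.sin(0.3), 0.0], rng)
        before = classify_orientation(p, ref_a, ref_b).label
        rot = Rotation.random(rng=np.random.default_rng(9))

        def rotated(lp):
            conf = lp.conformer.copy()
            conf.set_coords(rot.apply(conf.coords))
            return LigandPose(conf, lp.delta_g)

        after = classify_orientation(rotated(p), rotated(ref_a), rotated(ref_b)).label
        assert before == after

    def test_no_cation_or_ring_rejected(self, rng):
        ring = syn.make_toy_ligand("probe_ring")
        p = LigandPose(ring, -5.0)
        with pytest.raises(InputError):
            classify_orientation(p, p, p)

    def test_orientation_mix_recovered(self, pocket, mdma_like, rng):
        spec = syn.EnsembleSpec(
            n_poses=20, planted_frequencies=(), n_clusters=1,
            orientation_mix=(0.5, 0.3, 0.2), seed=7,
        )
        ens = syn.plant_pose_ensemble(pocket, mdma_like, spec)
        ref_a = self._ref(mdma_like, [1, 0, 0], rng)
        ref_b = self._ref(mdma_like, [-1, 0, 0], rng)
        from collections import Counter

        labels = Counter(
            classify_orientation(p, ref_a, ref_b).label for p in ens.poses
        )
        assert labels["serotonin_like"] == 10
        assert labels["escitalopram_like"] == 6
        assert labels["intermediate"] == 4
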