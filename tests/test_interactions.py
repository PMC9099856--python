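"""Typed-contact detection against brute-force oracles; profiles and
distance monitoring."""

import numpy as np
import pytest

from bindspace.geometry import angle_between, best_fit_plane, interplanar_angle
from bindspace.interactions import (
    ContactProfile,
    InteractionCriteria,
    MonitoredPair,
    contact_profile,
    detect_interactions,
    monitor_pair_distances,
    occurrence_table,
)
from bindspace.structures import (
    ActiveSite,
    Atom,
    InputError,
    Structure,
    assign_pharmacophore_types,
    perceive_bonds_and_rings,
)
from bindspace import synthetic as syn


def _benzene_at(center, normal_tilt_deg=0.0, residue=("A", 1, "PHE"), role="receptor"):
    """Planar six-ring; optionally tilted about the x axis."""
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    pts = []
    for i in range(6):
        a = np.deg2rad(60 * i)
        pts.append([1.39 * np.cos(a), 1.39 * np.sin(a), 0.0])
    pts = np.array(pts)
    t = np.deg2rad(normal_tilt_deg)
    rot = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])
    pts = pts @ rot.T + np.asarray(center, float)
    return Structure(
        atoms=[
            Atom(element="C", coords=p, name=names[i], residue_id=residue)
            for i, p in enumerate(pts)
        ],
        role=role,
    )


def _glu_with_oe1_at(pos):
    res = perceive_bonds_and_rings(syn.build_residue("GLU", ("A", 494, "GLU")))
    oe1 = next(a.coords for a in res.atoms if a.name == "OE1")
    return res.translated(np.asarray(pos, float) - oe1)


def _amine_pose():
    return syn.make_toy_ligand("probe_amine")


class TestDetection:
    def test_planted_salt_bridge_distance(self):
        pose = _amine_pose()
        n_pos = next(a.coords for a in pose.atoms if a.element == "N")
        receptor = _glu_with_oe1_at(n_pos + np.array([3.2, 0.0, 0.0]))
        site = ActiveSite(frozenset(receptor.residue_ids()), 6.0)
        records = detect_interactions(pose, receptor, site)
        salts = [r for r in records if r.kind == "salt_bridge"]
        assert any(abs(r.distance - 3.2) < 1e-6 for r in salts)

    @pytest.mark.parametrize("dist,expect", [(4.9, True), (5.1, False)])
    def test_pi_pi_centroid_cutoff(self, dist, expect):
        lig = _benzene_at([0, 0, 0], residue=("L", 1, "LIG"), role="ligand")
        perceive_bonds_and_rings(lig)
        rec = _benzene_at([0, 0, dist])
        perceive_bonds_and_rings(rec)
        site = ActiveSite(frozenset(rec.residue_ids()), 6.0)
        records = detect_interactions(lig, rec, site)
        pis = [r for r in records if r.kind.startswith("pi_pi")]
        assert bool(pis) is expect
        if expect:
            assert pis[0].kind == "pi_pi_parallel"
            assert pis[0].distance == pytest.approx(dist)

    def test_pi_classification_parallel_edge_displaced(self):
        lig = _benzene_at([0, 0, 0], residue=("L", 1, "LIG"), role="ligand")
        perceive_bonds_and_rings(lig)
        site = None
        for tilt, kind, displaced in [
            (10.0, "pi_pi_parallel", False),
            (85.0, "pi_pi_edge", False),
            (45.0, "pi_pi_parallel", True),
        ]:
            rec = _benzene_at([0, 0, 4.5], normal_tilt_deg=tilt)
            perceive_bonds_and_rings(rec)
            site = ActiveSite(frozenset(rec.residue_ids()), 6.0)
            pis = [
                r
                for r in detect_interactions(lig, rec, site)
                if r.kind.startswith("pi_pi")
            ]
            assert pis and pis[0].kind == kind and pis[0].displaced is displaced

    def test_strong_vs_weak_hbond_classification(self):
        lig = _amine_pose()
        n = next(i for i, a in enumerate(lig.atoms) if a.element == "N")
        h = next(
            i for i, a in enumerate(lig.atoms)
            if a.is_hydrogen and np.linalg.norm(a.coords - lig.atoms[n].coords) < 1.2
        )
        nh = lig.atoms[h].coords - lig.atoms[n].coords
        nh /= np.linalg.norm(nh)
        c = InteractionCriteria()
        # acceptor straight along N-H at 2.8 A: strong (angle ~180)
        rec_strong = _glu_with_oe1_at(lig.atoms[n].coords + 2.8 * nh)
        site = ActiveSite(frozenset(rec_strong.residue_ids()), 6.0)
        kinds = {r.kind for r in detect_interactions(lig, rec_strong, site, c)}
        assert "hbond_strong" in kinds
        # acceptor at 3.4 A: still an H-bond, but weak
        rec_weak = _glu_with_oe1_at(lig.atoms[n].coords + 3.4 * nh)
        kinds = {r.kind for r in detect_interactions(lig, rec_weak, site, c)}
        assert "hbond_weak" in kinds and "hbond_strong" not in kinds
        for rec in (rec_strong, rec_weak):
            for r in detect_interactions(lig, rec, site, c):
                if r.kind == "hbond_strong":
                    assert r.distance <= c.hbond_strong_dist
                    assert r.angle is None or r.angle >= c.hbond_strong_angle

    def test_shrinking_cutoffs_never_adds_records(self, pocket):
        lig = syn.make_toy_ligand("mdma_like").translated([0, 0, 1.0])
        site = ActiveSite(frozenset(pocket.residue_ids()), 6.0)
        wide = InteractionCriteria(
            hbond_max_dist=4.0, salt_bridge_max_dist=5.0,
            pi_centroid_max_dist=6.0, cation_pi_max_dist=6.0,
        )
        narrow = InteractionCriteria(
            hbond_max_dist=3.0, salt_bridge_max_dist=3.5,
            pi_centroid_max_dist=4.5, cation_pi_max_dist=4.5,
            hbond_strong_dist=3.0,
        )
        rng = np.random.default_rng(1)
        for _ in range(25):
            pose = lig.translated(rng.uniform(-5, 5, 3))
            wide_set = {
                (r.kind.replace("_weak", "").replace("_strong", ""), r.ligand_atoms, r.receptor_atoms)
                for r in detect_interactions(pose, pocket, site, wide)
            }
            narrow_set = {
                (r.kind.replace("_weak", "").replace("_strong", ""), r.ligand_atoms, r.receptor_atoms)
                for r in detect_interactions(pose, pocket, site, narrow)
            }
            assert narrow_set <= wide_set

    def test_matches_brute_force_oracle(self, pocket, mdma_like):
        """Independent all-pairs re-enumeration over every feature pair."""
        site = ActiveSite(frozenset(pocket.residue_ids()), 6.0)
        c = InteractionCriteria()
        rng = np.random.default_rng(7)
        rtags = assign_pharmacophore_types(pocket)
        for trial in range(12):
            pose = mdma_like.translated(rng.uniform(-6, 6, 3))
            got = {
                (r.kind, r.ligand_atoms, r.receptor_atoms, round(r.distance, 9))
                for r in detect_interactions(pose, pocket, site, c)
            }
            assert got == _oracle_records(pose, pocket, rtags, c)


def _oracle_records(pose, receptor, rtags, c):
    """Brute-force re-derivation written independently with plain loops."""
    out = set()
    ltags = assign_pharmacophore_types(pose)
    lxyz, rxyz = pose.coords, receptor.coords

    def group(tags, structure, xyz):
        cats, anis, dons, accs = {}, [], [], []
        for t in tags:
            if t.tag == "cation":
                cats.setdefault(structure.atoms[t.atom_index].residue_id, []).append(t.atom_index)
            elif t.tag == "anion":
                anis.append(t.atom_index)
            elif t.tag == "hbond_donor":
                dons.append((t.atom_index, t.h_index))
            elif t.tag == "hbond_acceptor":
                accs.append(t.atom_index)
        rings = []
        arom = {t.atom_index for t in tags if t.tag == "aromatic_ring_member"}
        if structure.rings:
            for ring in structure.rings:
                if set(ring.indices) <= arom:
                    pts = xyz[list(ring.indices)]
                    cen, nrm, _ = best_fit_plane(pts)
                    rings.append((tuple(ring.indices), cen, nrm))
        if not rings and arom:
            by_res = {}
            for i in arom:
                by_res.setdefault(structure.atoms[i].residue_id, []).append(i)
            for idxs in by_res.values():
                idxs = tuple(sorted(idxs))
                cen, nrm, _ = best_fit_plane(xyz[list(idxs)])
                rings.append((idxs, cen, nrm))
        cat_groups = [
            (tuple(sorted(v)), xyz[sorted(v)].mean(axis=0)) for v in cats.values()
        ]
        return cat_groups, sorted(anis), sorted(set(dons)), sorted(set(accs)), rings

    lc, la, ld, lacc, lr = group(ltags, pose, lxyz)
    rc, ra, rd, racc, rr = group(rtags, receptor, rxyz)

    def hb(dxyz, axyz, d, h, a, lig_donor, rid):
        dist = np.linalg.norm(dxyz[d] - axyz[a])
        if dist > c.hbond_max_dist or dist < 1e-6:
            return
        ang = None
        if h is not None:
            ang = angle_between(dxyz[d] - dxyz[h], axyz[a] - dxyz[h])
            if ang < c.hbond_min_angle:
                return
        strong = dist <= c.hbond_strong_dist and (ang is None or ang >= c.hbond_strong_angle)
        kind = "hbond_strong" if strong else "hbond_weak"
        da = tuple(x for x in (d, h) if x is not None)
        if lig_donor:
            out.add((kind, da, (a,), round(float(dist), 9)))
        else:
            out.add((kind, (a,), da, round(float(dist), 9)))

    for d, h in ld:
        for a in racc:
            hb(lxyz, rxyz, d, h, a, True, None)
    for d, h in rd:
        for a in lacc:
            hb(rxyz, lxyz, d, h, a, False, None)
    for idxs, cen in lc:
        for a in ra:
            dist = np.linalg.norm(cen - rxyz[a])
            if dist <= c.salt_bridge_max_dist:
                out.add(("salt_bridge", idxs, (a,), round(float(dist), 9)))
    for idxs, cen in rc:
        for a in la:
            dist = np.linalg.norm(cen - lxyz[a])
            if dist <= c.salt_bridge_max_dist:
                out.add(("salt_bridge", (a,), idxs, round(float(dist), 9)))
    for li, lcen, ln in lr:
        for ri, rcen, rn in rr:
            dist = np.linalg.norm(lcen - rcen)
            if dist > c.pi_centroid_max_dist:
                continue
            alpha = interplanar_angle(ln, rn)
            kind = (
                "pi_pi_parallel"
                if alpha <= c.pi_parallel_max_angle or alpha < c.pi_edge_min_angle
                else "pi_pi_edge"
            )
            out.add((kind, li, ri, round(float(dist), 9)))
    for idxs, cen in lc:
        for ri, rcen, _ in rr:
            dist = np.linalg.norm(cen - rcen)
            if dist <= c.cation_pi_max_dist:
                out.add(("cation_pi", idxs, ri, round(float(dist), 9)))
    for idxs, cen in rc:
        for li, lcen, _ in lr:
            dist = np.linalg.norm(cen - lcen)
            if dist <= c.cation_pi_max_dist:
                out.add(("cation_pi", li, idxs, round(float(dist), 9)))
    return out


class TestProfiles:
    def test_simple_counting(self, pocket, mdma_like, full_site):
        # 10 poses, 7 planted on GLU
        spec = syn.EnsembleSpec(
            n_poses=10,
            planted_frequencies=((("A", 494, "GLU"), 0.7),),
            seed=5,
        )
        ens = syn.plant_pose_ensemble(pocket, mdma_like, spec)
        prof = contact_profile([p.conformer for p in ens.poses], pocket, full_site)
        assert prof.occurrence[("A", 494, "GLU")] == pytest.approx(0.7)
        assert prof.n_poses == 10

    def test_occurrence_times_n_is_integer(self, pocket, mdma_like, full_site):
        ens = syn.plant_pose_ensemble(pocket, mdma_like, syn.EnsembleSpec(n_poses=23, seed=2))
        prof = contact_profile([p.conformer for p in ens.poses], pocket, full_site)
        for v in prof.occurrence.values():
            assert abs(v * prof.n_poses - round(v * prof.n_poses)) < 1e-9

    def test_single_pose_all_ones(self, pocket, mc_system):
        pose = mc_system[0]
        prof = contact_profile([pose], mc_system[1], mc_system[2])
        assert prof.occurrence and all(v == 1.0 for v in prof.occurrence.values())

    def test_invariant_under_reordering_and_mode_ordering(self, pocket, mdma_like, full_site):
        ens = syn.plant_pose_ensemble(pocket, mdma_like, syn.EnsembleSpec(n_poses=30, seed=9))
        poses = [p.conformer for p in ens.poses]
        a = contact_profile(poses, pocket, full_site)
        b = contact_profile(list(reversed(poses)), pocket, full_site)
        assert a.occurrence == b.occurrence
        typed = contact_profile(poses, pocket, full_site, mode="typed_only")
        any_c = contact_profile(poses, pocket, full_site, mode="any_contact")
        for rid, v in typed.occurrence.items():
            assert v <= any_c.occurrence.get(rid, 0.0) + 1e-12

    def test_empty_ensemble_rejected(self, pocket, full_site):
        with pytest.raises(InputError):
            contact_profile([], pocket, full_site)


class TestOccurrenceTable:
    def test_totals_conserved(self, pocket, mdma_like, full_site):
        ens = syn.plant_pose_ensemble(pocket, mdma_like, syn.EnsembleSpec(n_poses=25, seed=4))
        per_pose = [
            detect_interactions(p.conformer, pocket, full_site) for p in ens.poses
        ]
        table = occurrence_table(per_pose)
        assert int(table.to_numpy().sum()) == sum(len(r) for r in per_pose)
        # brute-force recount per (residue, kind)
        for rid in table.index:
            for kind in table.columns:
                expected = sum(
                    1 for recs in per_pose for r in recs
                    if r.residue_id == rid and r.kind == kind
                )
                assert table.loc[rid, kind] == expected


class TestDistanceMonitoring:
    def test_series_tracks_translation(self, mc_system):
        from bindspace.mc import MCConfig, MCTrajectory, MCStep

        pose, receptor, site, pairs = mc_system
        k = 3
        snaps = [pose.copy() for _ in range(6)]
        for s in snaps[k + 1 :]:
            s.set_coords(s.coords + np.array([0.0, 0.0, 1.0]))
        traj = MCTrajectory(
            steps=[MCStep(i, 0.0, 0.0, True, np.zeros(3)) for i in range(5)],
            snapshots=snaps,
            receptor=receptor,
            config=MCConfig(n_steps=5),
        )
        series = monitor_pair_distances(traj, pairs)
        for s in series:
            assert len(s.values) == 5
            assert np.allclose(s.values[:k], s.values[0])
            assert not np.allclose(s.values[k], s.values[0])

    def test_tidy_export_long_format(self):
        from bindspace.interactions import DistanceSeries, distance_series_frame

        series = [
            DistanceSeries("a", np.array([3.0, 3.1])),
            DistanceSeries("b", np.array([4.0, 4.2])),
        ]
        df = distance_series_frame(series)
        assert list(df.columns) == ["step", "pair", "distance"]
        assert len(df) == 4
        assert df[df.pair == "b"].distance.tolist() == [4.0, 4.2]

    def test_invalid_pair_rejected(self, mc_system):
        from bindspace.mc import MCConfig, MCTrajectory

        pose, receptor, site, _ = mc_system
        traj = MCTrajectory(steps=[], snapshots=[pose], receptor=receptor,
                            config=MCConfig(n_steps=0))
        bad = MonitoredPair("bad", (999,), (0,))
        with pytest.raises(InputError):
            monitor_pair_distances(traj, [bad])
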