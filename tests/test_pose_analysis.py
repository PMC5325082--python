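"""Cation-pi / H-bond detection, pose classification, clustering, summaries."""

import math

import numpy as np
import pytest

import pentasite as ps
from pentasite.pose_analysis import pose_rmsd, report_table, write_pose_table

from conftest import random_rigid_transform


def _hexagon_xy(center, radius=1.39):
    return [np.array(center) + radius * np.array(
        [math.cos(math.radians(60 * k)), math.sin(math.radians(60 * k)), 0.0])
        for k in range(6)]


def _trp_model(torpedo=149):
    """One TRP ring in the xy-plane at the origin, plus an inert B chain."""
    names = ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")
    atoms = [ps.Atom(n, "C", c) for n, c in zip(names, _hexagon_xy((0, 0, 0)))]
    trp = ps.Residue("A", torpedo, "TRP", atoms, torpedo_number=torpedo)
    gly = ps.Residue("B", 1, "GLY", [ps.Atom("CA", "C", np.array([30.0, 0, 0]))])
    model = ps.StructureModel([ps.Chain("A", "a9", [trp]), ps.Chain("B", "a9", [gly])])
    iface = ps.InterfaceSpec("A", "B", "a9(+)a9(-)")
    return model, iface


def _n_pose(coords, energy=-5.0):
    return ps.LigandPose("p1", [ps.Atom("N", "N", np.asarray(coords, float))], energy)


class TestCationPi:
    def test_n_on_ring_axis_gives_exact_distance_and_zero_angle(self):
        model, iface = _trp_model()
        contacts = ps.detect_cation_pi(_n_pose([0, 0, 4.0]), model, iface)
        assert len(contacts) == 1
        c = contacts[0]
        assert c.torpedo_number == 149 and c.residue_name == "TRP"
        assert c.distance == pytest.approx(4.0, abs=1e-9)
        assert c.axial_angle == pytest.approx(0.0, abs=1e-6)

    def test_beyond_distance_cutoff_is_empty(self):
        model, iface = _trp_model()
        assert ps.detect_cation_pi(_n_pose([0, 0, 8.0]), model, iface) == []

    def test_in_plane_placement_fails_angle_criterion(self):
        model, iface = _trp_model()
        assert ps.detect_cation_pi(_n_pose([5.0, 0, 0]), model, iface) == []

    def test_custom_thresholds_admit_in_plane_contact(self):
        model, iface = _trp_model()
        geom = ps.GeomConfig(theta_max=95.0)
        contacts = ps.detect_cation_pi(_n_pose([5.0, 0, 0]), model, iface, geom)
        assert len(contacts) == 1
        assert contacts[0].axial_angle == pytest.approx(90.0, abs=1e-6)

    def test_incomplete_ring_is_skipped_with_warning(self):
        model, iface = _trp_model()
        del model.chain("A").residues[0].atoms[0]
        with pytest.warns(UserWarning, match="missing ring atoms"):
            assert ps.detect_cation_pi(_n_pose([0, 0, 4.0]), model, iface) == []

    def test_planted_pocket_aromatics_report_planted_geometry(
            self, toy_bundle, toy_ligand_pose):
        model, iface, truth = toy_bundle
        geom = ps.GeomConfig(d_max=6.0)
        contacts = ps.detect_cation_pi(toy_ligand_pose, model, iface, geom)
        by_num = {c.torpedo_number: c for c in contacts}
        for num in (55, 93, 149, 190):
            plant = truth["plants"][num]
            assert by_num[num].distance == pytest.approx(plant["distance"], abs=1e-9)
            assert by_num[num].axial_angle == pytest.approx(plant["angle_deg"], abs=1e-6)


class TestHBonds:
    def _tyr_model(self, oh_coords):
        tyr = ps.Residue("A", 197, "TYR",
                         [ps.Atom("OH", "O", np.asarray(oh_coords, float))],
                         torpedo_number=197)
        gly = ps.Residue("B", 1, "GLY", [ps.Atom("CA", "C", np.array([30.0, 0, 0]))])
        model = ps.StructureModel([ps.Chain("A", "a9", [tyr]),
                                   ps.Chain("B", "a9", [gly])])
        return model, ps.InterfaceSpec("A", "B", "a9(+)a9(-)")

    def _ester_pose(self):
        return ps.LigandPose("p1", [ps.Atom("N", "N", np.zeros(3)),
                                    ps.Atom("O1", "O", np.array([2.0, 0, 0]))], -5.0)

    def test_distance_only_contact_without_hydrogens(self):
        model, iface = self._tyr_model([4.8, 0, 0])  # 2.8 A from O1
        contacts = ps.detect_hbonds(self._ester_pose(), model, iface)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(2.8)
        assert contacts[0].torpedo_number == 197

    def test_beyond_cutoff_is_empty(self):
        model, iface = self._tyr_model([6.2, 0, 0])  # 4.2 A from O1
        assert ps.detect_hbonds(self._ester_pose(), model, iface) == []

    def test_planted_asp119_and_tyr197_both_reported(self):
        spec = ps.ToyPocketSpec([
            ps.PlantedResidue(119, "ASP", "complementary", "hbond", 3.0),
            ps.PlantedResidue(197, "TYR", "principal", "hbond", 3.1),
        ])
        model, iface, truth = ps.gen_toy_pentamer(spec)
        lig = next(r for c in model.chains for r in c.residues if r.is_ligand)
        pose = ps.LigandPose("lig", list(lig.atoms), 0.0)
        geom = ps.GeomConfig(ligand_polar_atoms=("O1",))
        contacts = ps.detect_hbonds(pose, model, iface, geom)
        assert {c.torpedo_number for c in contacts} == {119, 197}
        dists = {c.torpedo_number: c.distance for c in contacts}
        assert dists[119] == pytest.approx(3.0, abs=1e-9)
        assert dists[197] == pytest.approx(3.1, abs=1e-9)


class TestClassification:
    def test_single_aromatic_contact_is_favorable(self):
        model, iface = _trp_model(torpedo=149)
        report = ps.classify_pose(_n_pose([0, 0, 4.0]), model, iface)
        assert report.favorable and len(report.cation_pi_contacts) == 1

    def test_hbonds_alone_do_not_make_a_pose_favorable(self):
        spec = ps.ToyPocketSpec([
            ps.PlantedResidue(119, "ASP", "complementary", "hbond", 3.0),
            ps.PlantedResidue(197, "TYR", "principal", "hbond", 3.1),
        ])
        model, iface, _ = ps.gen_toy_pentamer(spec)
        lig = next(r for c in model.chains for r in c.residues if r.is_ligand)
        report = ps.classify_pose(ps.LigandPose("lig", list(lig.atoms), 0.0),
                                  model, iface)
        assert not report.favorable

    def test_contact_outside_key_aromatic_set_does_not_count(self):
        model, iface = _trp_model(torpedo=200)  # aromatic, but not in {55,93,149,190}
        report = ps.classify_pose(_n_pose([0, 0, 4.0]), model, iface)
        assert report.cation_pi_contacts and not report.favorable

    def test_classifier_recovers_planted_labels(self, toy_bundle):
        model, iface, _ = toy_bundle
        cfg = ps.PoseSimConfig(n_poses=100, favorable_fraction=0.3)
        ensemble, labels = ps.gen_pose_ensemble(cfg, model, iface, seed=7)
        verdicts = [ps.classify_pose(p, model, iface).favorable
                    for p in ensemble.poses]
        assert verdicts == labels


def _random_ensemble(rng, n_poses=10, n_atoms=5, spread=3.0):
    poses = []
    for i in range(n_poses):
        center = rng.uniform(-spread, spread, size=3)
        atoms = [ps.Atom(f"C{j}", "C", center + rng.normal(0, 0.5, size=3))
                 for j in range(n_atoms)]
        poses.append(ps.LigandPose(f"p{i:02d}", atoms, float(rng.normal(-5, 1))))
    return ps.PoseEnsemble(None, poses, n_runs=n_poses)


def _oracle_greedy(poses, cutoff):
    """Independent brute-force greedy clustering (quadratic, list-based)."""
    def rmsd(a, b):
        ca = np.stack([x.coords for x in a.atoms])
        cb = np.stack([x.coords for x in b.atoms])
        return math.sqrt(float(np.mean(np.sum((ca - cb) ** 2, axis=1))))

    remaining = sorted(poses, key=lambda p: (p.binding_energy, p.pose_id))
    clusters = []
    while remaining:
        seed = remaining[0]
        members = [p for p in remaining if rmsd(seed, p) <= cutoff]
        clusters.append([p.pose_id for p in members])
        remaining = [p for p in remaining if p.pose_id not in
                     {m for m in clusters[-1]}]
    return clusters


class TestClustering:
    def test_single_pose_single_cluster(self):
        ens = ps.PoseEnsemble(None, [_n_pose([0, 0, 0])], n_runs=1)
        clusters = ps.cluster_poses(ens)
        assert len(clusters) == 1 and clusters[0].member_ids == ["p1"]

    def test_identical_poses_merge_at_zero_rmsd(self):
        a = _n_pose([1, 1, 1], energy=-5.0)
        b = ps.LigandPose("p2", [ps.Atom("N", "N", np.array([1.0, 1, 1]))], -4.0)
        clusters = ps.cluster_poses(ps.PoseEnsemble(None, [a, b], n_runs=2))
        assert len(clusters) == 1
        assert clusters[0].seed_id == "p1"  # lower energy seeds the cluster

    def test_matches_brute_force_oracle_on_random_ensembles(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ens = _random_ensemble(rng)
            ours = [c.member_ids for c in ps.cluster_poses(ens, 2.0)]
            assert ours == _oracle_greedy(ens.poses, 2.0)

    def test_cluster_invariants(self):
        rng = np.random.default_rng(3)
        ens = _random_ensemble(rng, n_poses=20)
        clusters = ps.cluster_poses(ens, 2.0)
        by_id = {p.pose_id: p for p in ens.poses}
        seen = []
        energies = [c.seed_energy for c in clusters]
        assert energies == sorted(energies)
        for c in clusters:
            seed = by_id[c.seed_id]
            for mid in c.member_ids:
                assert pose_rmsd(seed, by_id[mid]) <= 2.0
                seen.append(mid)
        assert sorted(seen) == sorted(by_id)

    def test_inconsistent_atom_counts_rejected(self):
        a = _n_pose([0, 0, 0])
        b = ps.LigandPose("p2", [ps.Atom("N", "N", np.zeros(3)),
                                 ps.Atom("C1", "C", np.ones(3))], -4.0)
        with pytest.raises(ValueError, match="atom counts"):
            ps.cluster_poses(ps.PoseEnsemble(None, [a, b], n_runs=2))


class TestSummaries:
    def test_four_favorable_of_200_is_two_percent(self, toy_bundle):
        model, iface, _ = toy_bundle
        cfg = ps.PoseSimConfig(n_poses=200, favorable_fraction=0.02)
        ensemble, labels = ps.gen_pose_ensemble(cfg, model, iface, seed=5)
        reports = [ps.classify_pose(p, model, iface) for p in ensemble.poses]
        summary = ps.summarize_interface(ensemble, reports)
        assert sum(labels) == 4
        assert summary.favorable_frequency == pytest.approx(2.0)

    def test_bbe_is_the_minimum_energy_and_order_invariant(self):
        poses = [ps.LigandPose(f"p{i}", [ps.Atom("N", "N", np.array([float(i), 0, 0]))], e)
                 for i, e in enumerate([-5.1, -4.8, -3.3])]
        reports = [ps.InteractionReport(p.pose_id, [], [], False) for p in poses]
        fwd = ps.summarize_interface(ps.PoseEnsemble(None, poses, 3), reports)
        rev = ps.summarize_interface(ps.PoseEnsemble(None, poses[::-1], 3),
                                     reports[::-1])
        assert fwd.bbe == rev.bbe == pytest.approx(-5.1)

    def test_replicate_average_matches_planted_frequencies(self, toy_bundle):
        model, iface, _ = toy_bundle
        summaries = []
        for seed, frac in zip((1, 2, 3), (0.10, 0.12, 0.14)):
            cfg = ps.PoseSimConfig(n_poses=100, favorable_fraction=frac)
            ens, _ = ps.gen_pose_ensemble(cfg, model, iface, seed=seed)
            reports = [ps.classify_pose(p, model, iface) for p in ens.poses]
            summaries.append(ps.summarize_interface(ens, reports))
        avg = ps.average_summaries(summaries)
        assert avg["favorable_frequency_mean"] == pytest.approx(12.0)
        assert avg["n_replicates"] == 3

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="n_runs"):
            ps.PoseEnsemble(None, [], n_runs=0)
        ens = ps.PoseEnsemble(None, [], n_runs=10)
        with pytest.raises(ValueError, match="empty"):
            ps.summarize_interface(ens, [])


MULTI_MODEL_PDB = """\
MODEL        1
REMARK  Energy = -5.10
HETATM    1  N   ACH L   1       0.000   0.000   0.000  1.00  0.00           N
HETATM    2  C1  ACH L   1       1.470   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
REMARK  Energy = -4.80
HETATM    1  N   ACH L   1       0.500   0.000   0.000  1.00  0.00           N
HETATM    2  C1  ACH L   1       1.970   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        3
REMARK  Energy = -3.30
HETATM    1  N   ACH L   1       9.000   0.000   0.000  1.00  0.00           N
HETATM    2  C1  ACH L   1      10.470   0.000   0.000  1.00  0.00           C
ENDMDL
"""

DLG_EXCERPT = """\
DOCKED: MODEL        1
DOCKED: USER    Estimated Free Energy of Binding    =   -5.20 kcal/mol
DOCKED: ROOT
DOCKED: ATOM      1  N   ACH     1       1.000   2.000   3.000  0.00  0.00    +0.250 N
DOCKED: ATOM      2  C1  ACH     1       2.470   2.000   3.000  0.00  0.00    +0.050 C
DOCKED: ENDMDL
DOCKED: MODEL        2
DOCKED: USER    Estimated Free Energy of Binding    =   -3.95 kcal/mol
DOCKED: ROOT
DOCKED: ATOM      1  N   ACH     1       5.000   2.000   3.000  0.00  0.00    +0.250 N
DOCKED: ATOM      2  C1  ACH     1       6.470   2.000   3.000  0.00  0.00    +0.050 C
DOCKED: ENDMDL
"""


class TestPoseIO:
    def test_multimodel_pdb_keeps_order_and_energies(self):
        ens = ps.read_pose_file(MULTI_MODEL_PDB)
        assert [p.binding_energy for p in ens.poses] == [-5.10, -4.80, -3.30]
        assert [p.pose_id for p in ens.poses] == ["pose001", "pose002", "pose003"]

    def test_missing_energy_names_the_pose(self):
        broken = MULTI_MODEL_PDB.replace("REMARK  Energy = -4.80\n", "")
        with pytest.raises(ValueError, match="pose 2"):
            ps.read_pose_file(broken)

    def test_dlg_excerpt_matches_energies_to_blocks(self):
        ens = ps.read_pose_file(DLG_EXCERPT)
        assert len(ens.poses) == 2
        assert [p.binding_energy for p in ens.poses] == [-5.20, -3.95]
        np.testing.assert_allclose(ens.poses[0].atoms[0].coords, [1, 2, 3])

    def test_table_round_trip(self, toy_bundle):
        model, iface, _ = toy_bundle
        cfg = ps.PoseSimConfig(n_poses=5, favorable_fraction=0.4)
        ens, _ = ps.gen_pose_ensemble(cfg, model, iface, seed=2)
        back = ps.read_pose_file(write_pose_table(ens))
        assert [p.pose_id for p in back.poses] == [p.pose_id for p in ens.poses]
        for a, b in zip(ens.poses, back.poses):
            assert b.binding_energy == pytest.approx(a.binding_energy)
            np.testing.assert_allclose(b.coords(), a.coords(), atol=1e-9)

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ValueError, match="dialect"):
            ps.read_pose_file("just some words")

    def test_report_table_has_one_row_per_pose(self):
        reports = [ps.InteractionReport("a", [], [], False),
                   ps.InteractionReport("b", [], [], True)]
        table = report_table(reports)
        assert list(table["pose_id"]) == ["a", "b"]
        assert list(table["favorable"]) == [False, True]


class TestRigidInvariance:
    def test_contacts_preserved_under_rigid_motion(self, toy_bundle, toy_ligand_pose):
        model, iface, _ = toy_bundle
        rng = np.random.default_rng(42)
        base_cpi = ps.detect_cation_pi(toy_ligand_pose, model, iface)
        base_hb = ps.detect_hbonds(toy_ligand_pose, model, iface)
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            m2 = model.transformed(rot, trans)
            p2 = toy_ligand_pose.transformed(rot, trans)
            cpi = ps.detect_cation_pi(p2, m2, iface)
            hb = ps.detect_hbonds(p2, m2, iface)
            assert [(c.torpedo_number, round(c.distance, 6), round(c.axial_angle, 5))
                    for c in cpi] == [(c.torpedo_number, round(c.distance, 6),
                                       round(c.axial_angle, 5)) for c in base_cpi]
            assert [(c.torpedo_number, round(c.distance, 6)) for c in hb] == \
                   [(c.torpedo_number, round(c.distance, 6)) for c in base_hb]
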