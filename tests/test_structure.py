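"""Coordinate I/O, superposition, helix-motion decomposition, interaction
detection and the microswitch report."""

import numpy as np
import pytest

from gpcrkit.compare import (InteractionCriteria, detect_interactions,
                             helix_axis, helix_rotation_retraction,
                             microswitch_report, superpose)
from gpcrkit.helix import HelixFixtureSpec, make_helix_fixture
from gpcrkit.structure import (StructureModel, Transform, read_structure,
                               write_structure)

ALTLOC_PDB = """\
ATOM      1  N   SER A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA ASER A   1      11.639   6.071  -5.147  0.60  0.00           C
ATOM      3  CA BSER A   1      11.700   6.200  -5.000  0.40  0.00           C
ATOM      4  C   SER A   1      12.759   7.092  -4.990  1.00  0.00           C
ATOM      5  O   SER A   1      13.023   7.918  -5.858  1.00  0.00           O
END
"""


class TestIO:
    def test_pdb_round_trip_preserves_coordinates(self, helix_base, tmp_path):
        p = tmp_path / "helix.pdb"
        write_structure(helix_base, p)
        back = read_structure(p)
        assert back.n_atoms == helix_base.n_atoms
        assert np.abs(back.coords - helix_base.coords).max() <= 1e-3
        # second round trip is exact at file precision
        p2 = tmp_path / "helix2.pdb"
        write_structure(back, p2)
        again = read_structure(p2)
        assert np.array_equal(again.coords, back.coords)

    def test_mmcif_dialect(self, helix_base, tmp_path):
        import gemmi

        p = tmp_path / "helix.pdb"
        write_structure(helix_base, p)
        st = gemmi.read_structure(str(p))
        st.setup_entities()
        cif = tmp_path / "helix.cif"
        st.make_mmcif_document().write_file(str(cif))
        back = read_structure(cif, fmt="mmcif")
        assert back.n_atoms == helix_base.n_atoms
        assert np.abs(back.coords - helix_base.coords).max() <= 1e-3

    def test_helix_fixture_shape(self, helix_base):
        assert helix_base.n_atoms == 20
        assert set(helix_base.name) == {"CA"}
        assert helix_base.chains() == ["A"]

    def test_altloc_highest_occupancy(self, tmp_path):
        p = tmp_path / "altloc.pdb"
        p.write_text(ALTLOC_PDB)
        m = read_structure(p, altloc_policy="occupancy")
        ca = m.residue_atoms("A", 1)
        names = list(m.name[ca])
        assert names.count("CA") == 1
        i = ca[np.asarray(m.name[ca]) == "CA"][0]
        assert m.occupancy[i] == pytest.approx(0.60)
        m_all = read_structure(p, altloc_policy="all")
        assert list(m_all.name).count("CA") == 2

    def test_unparseable_file_raises_with_context(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            read_structure(bad, fmt="mmcif")


class TestSuperpose:
    def test_identity(self, helix_base):
        tr, r = superpose(helix_base, helix_base, "chain A")
        assert r == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_known_transform_recovered(self, helix_base):
        applied = Transform.from_axis_angle([1, -2, 0.5], 63.0,
                                            translation=[4, 5, -6])
        moved = helix_base.transformed(applied)
        rec, r = superpose(moved, helix_base, "chain A")
        assert r == pytest.approx(0.0, abs=1e-9)
        comp = rec.compose(applied)
        assert np.abs(comp.rotation - np.eye(3)).max() <= 1e-6
        assert np.abs(comp.translation).max() <= 1e-6

    def test_collinear_selection_rejected(self):
        m = StructureModel.from_arrays(
            chain=["A"] * 4, resid=[1, 2, 3, 4], resname=["GLY"] * 4,
            name=["CA"] * 4, element=["C"] * 4,
            coords=[[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            superpose(m, m, "chain A")

    def test_transform_inverse_composes_to_identity(self):
        tr = Transform.from_axis_angle([3, 1, 2], 117.0, translation=[1, 2, 3])
        comp = tr.compose(tr.inverse())
        assert np.abs(comp.rotation - np.eye(3)).max() <= 1e-9
        assert np.abs(comp.translation).max() <= 1e-9


class TestHelixGeometry:
    def test_axis_of_ideal_helix_is_z(self, helix_base):
        axis, centroid = helix_axis(helix_base, "chain A")
        assert axis @ np.array([0, 0, 1.0]) >= 0.9999

    def test_axis_rotates_with_fixture(self, helix_base):
        tr = Transform.from_axis_angle([1, 1, 0], 40.0)
        moved = helix_base.transformed(tr)
        axis0, _ = helix_axis(helix_base, "chain A")
        axis1, _ = helix_axis(moved, "chain A")
        expected = tr.rotation @ axis0
        ang = np.rad2deg(np.arccos(np.clip(axis1 @ expected, -1, 1)))
        assert ang <= 0.1

    def test_too_few_residues_error(self):
        small = make_helix_fixture(HelixFixtureSpec(n_residues=5))
        with pytest.raises(ValueError):
            helix_axis(small, "chain A")

    def test_identical_states_give_null_change(self, helix_base):
        ch = helix_rotation_retraction(helix_base, helix_base, "chain A")
        assert ch.tilt == pytest.approx(0.0, abs=1e-5)  # arccos precision floor
        assert ch.spin == pytest.approx(0.0, abs=1e-9)
        assert ch.retraction == pytest.approx(0.0, abs=1e-9)

    def test_spin_and_retraction_recovered(self, helix_base):
        moved = make_helix_fixture(HelixFixtureSpec(n_residues=20,
                                                    spin_deg=8.0, shift_a=2.0))
        ch = helix_rotation_retraction(helix_base, moved, "chain A")
        assert ch.spin == pytest.approx(8.0, abs=0.5)
        assert ch.retraction == pytest.approx(2.0, abs=0.05)
        assert ch.tilt <= 0.5

    def test_recovery_with_alignment_frame(self, helix_base):
        # same motion, but both states also carry a shared rigid offset and a
        # separate anchor domain used for alignment
        anchor = StructureModel.from_arrays(
            chain=["B"] * 4, resid=[1, 2, 3, 4], resname=["GLY"] * 4,
            name=["CA"] * 4, element=["C"] * 4,
            coords=[[10, 0, -5], [10, 4, -5], [14, 0, -5], [10, 0, -9]])

        def combine(helix, tr=None):
            c = np.vstack([helix.coords, anchor.coords])
            m = StructureModel.from_arrays(
                chain=list(helix.chain) + list(anchor.chain),
                resid=list(helix.resid) + list(anchor.resid),
                resname=["ALA"] * 20 + ["GLY"] * 4,
                name=["CA"] * 24, element=["C"] * 24, coords=c)
            return m.transformed(tr) if tr else m

        moved = make_helix_fixture(HelixFixtureSpec(n_residues=20,
                                                    spin_deg=5.0, shift_a=1.5))
        rigid = Transform.from_axis_angle([2, 1, 1], 75.0, translation=[8, -3, 2])
        a = combine(helix_base)
        b = combine(moved, rigid)
        ch = helix_rotation_retraction(a, b, "chain A", align_selection="chain B")
        assert ch.spin == pytest.approx(5.0, abs=0.5)
        assert abs(ch.retraction) == pytest.approx(1.5, abs=0.05)


def _arg_glu_pair(n_dist=3.0):
    coords = [[0, 0, 0], [1, 1, 0], [1, -1, 0], [0.7, 0, 0],
              [n_dist, 1, 0], [n_dist + 1, -1, 0], [n_dist + 0.5, 0, 0]]
    return StructureModel.from_arrays(
        chain=["A"] * 7, resid=[10] * 4 + [20] * 3,
        resname=["ARG"] * 4 + ["GLU"] * 3,
        name=["NE", "NH1", "NH2", "CZ", "OE1", "OE2", "CD"],
        element=["N", "N", "N", "C", "O", "O", "C"], coords=coords)


def _ring(center, normal_axis="z", resname="PHE", resid=30, chain="A"):
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    ring = np.column_stack([1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)])
    ring += np.asarray(center)
    names = list(RINGNAMES[resname])
    return ring, names


RINGNAMES = {"PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")}


class TestInteractions:
    def test_salt_bridge_detected(self):
        df = detect_interactions(_arg_glu_pair(3.0))
        assert "salt_bridge" in set(df["type"])
        row = df[df["type"] == "salt_bridge"].iloc[0]
        assert row["distance_A"] <= 4.0

    def test_weak_hbond_at_4A_not_strong(self):
        coords = [[0, 0, 0], [4.0, 0, 0]]
        m = StructureModel.from_arrays(
            chain=["A", "A"], resid=[59, 369], resname=["GLN", "THR"],
            name=["NE2", "OG1"], element=["N", "O"], coords=coords)
        df = detect_interactions(m)
        assert set(df["type"]) == {"weak_hbond"}
        assert df.iloc[0]["distance_A"] == pytest.approx(4.0)

    def test_cation_pi_detected(self):
        ring, names = _ring([0, 0, 0])
        cat = np.array([[4.2 * np.sin(np.deg2rad(15)), 0,
                         4.2 * np.cos(np.deg2rad(15))]])
        coords = np.vstack([ring, cat])
        m = StructureModel.from_arrays(
            chain=["A"] * 7, resid=[30] * 6 + [40],
            resname=["PHE"] * 6 + ["LYS"],
            name=names + ["NZ"], element=["C"] * 6 + ["N"], coords=coords)
        df = detect_interactions(m)
        hit = df[df["type"] == "cation_pi"]
        assert len(hit) == 1
        assert hit.iloc[0]["distance_A"] == pytest.approx(4.2, abs=1e-6)
        assert hit.iloc[0]["angle_deg"] == pytest.approx(15.0, abs=0.1)

    def test_ch3_pi_range(self):
        ring, names = _ring([0, 0, 0])
        for d, expect in ((4.0, True), (6.5, False)):
            coords = np.vstack([ring, [[0, 0, d]]])
            m = StructureModel.from_arrays(
                chain=["A"] * 7, resid=[30] * 6 + [60],
                resname=["PHE"] * 6 + ["MET"],
                name=names + ["CE"], element=["C"] * 6 + ["C"], coords=coords)
            df = detect_interactions(m)
            assert ("ch3_pi" in set(df["type"])) == expect

    def test_report_is_deterministic_and_canonical(self):
        m = _arg_glu_pair(3.0)
        a = detect_interactions(m)
        b = detect_interactions(m)
        assert a.equals(b)
        assert list(a["type"]) == sorted(a["type"])

    def test_unknown_residue_warns_not_silent(self):
        m = StructureModel.from_arrays(
            chain=["A"], resid=[1], resname=["XYZ"], name=["C1"],
            element=["C"], coords=[[0, 0, 0]])
        with pytest.warns(UserWarning, match="XYZ"):
            detect_interactions(m)

    def test_rigid_motion_invariance(self):
        m = _arg_glu_pair(3.0)
        tr = Transform.from_axis_angle([1, 2, 3], 85.0, translation=[5, -7, 2])
        a = detect_interactions(m)
        b = detect_interactions(m.transformed(tr))
        assert np.allclose(a["distance_A"], b["distance_A"], atol=1e-9)


class TestMicroswitches:
    def _tyr_pair(self, d):
        coords = [[0, 0, 0], [d, 0, 0]]
        return StructureModel.from_arrays(
            chain=["A", "A"], resid=[197, 288], resname=["TYR", "TYR"],
            name=["OH", "OH"], element=["O", "O"], coords=coords)

    def test_tyr_pair_hbond_call(self):
        m = self._tyr_pair(2.8)
        rep = microswitch_report(m, {"5.58": ("A", 197), "7.53": ("A", 288)})
        row = rep[rep["motif"] == "Y5.58-Y7.53 OH"].iloc[0]
        assert row["status"] == "ok"
        assert row["call"] == "hbond"
        assert row["value"] == pytest.approx(2.8)

    def test_missing_positions_flagged_rows_still_computed(self):
        m = self._tyr_pair(3.9)
        rep = microswitch_report(m, {"5.58": ("A", 197), "7.53": ("A", 288)})
        assert (rep[rep["motif"] == "Y5.58-Y7.53 OH"]["call"] == "weak_hbond").all()
        missing = rep[rep["status"] == "missing"]
        assert len(missing) >= 2  # PIF and CWxP rows lack mapped residues

    def test_pif_distance_and_no_false_ch3_pi(self):
        ring, names = _ring([0, 0, 0])
        coords = np.vstack([ring, [[0, 0, 6.5]]])
        m = StructureModel.from_arrays(
            chain=["A"] * 7, resid=[129] * 6 + [92],
            resname=["PHE"] * 6 + ["ILE"],
            name=names + ["CD1"], element=["C"] * 7, coords=coords)
        rep = microswitch_report(m, {"6.44": ("A", 129), "3.40": ("A", 92)})
        row = rep[rep["motif"] == "PIF 3.40-6.44"].iloc[0]
        assert row["status"] == "ok"
        assert row["value"] == pytest.approx(6.5, abs=1e-6)
        df = detect_interactions(m)
        assert "ch3_pi" not in set(df["type"])
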