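"""Torsion math, hydrogen placement, and the ideal-peptide builder."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from helixsurvey import (
    GEOMETRY_SETS,
    TorsionTriple,
    backbone_torsions,
    build_peptide,
    dihedral,
    generate_fixture_archive,
    parse_pdb,
    place_amide_hydrogens,
)
from helixsurvey.backbone_geometry import GeometryError, bond_angle, place_atom

P1 = np.array([0.0, 1.0, 0.0])
P2 = np.array([0.0, 0.0, 0.0])
P3 = np.array([1.5, 0.0, 0.0])


class TestDihedral:
    def test_cis_is_zero(self):
        assert dihedral(P1, P2, P3, np.array([1.5, 1.0, 0.0])) == pytest.approx(0.0)

    def test_trans_is_180(self):
        assert dihedral(P1, P2, P3, np.array([1.5, -1.0, 0.0])) == pytest.approx(180.0)

    def test_explicit_rotation_gives_plus_90(self):
        # rotate the cis endpoint +90 deg (right-handed) about the p2->p3 axis
        axis = (P3 - P2) / np.linalg.norm(P3 - P2)
        rot = Rotation.from_rotvec(np.deg2rad(90.0) * axis)
        p4 = P3 + rot.apply(np.array([1.5, 1.0, 0.0]) - P3)
        assert dihedral(P1, P2, P3, p4) == pytest.approx(90.0, abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_coincident_raises(self):
        with pytest.raises(GeometryError):
            dihedral(P1, P2, P2, P3)

    @given(st.floats(min_value=-179.0, max_value=179.0))
    @settings(max_examples=50, derandomize=True)
    def test_place_atom_round_trip(self, torsion):
        d = place_atom(P1, P2, P3, 1.4, 112.0, torsion)
        assert dihedral(P1, P2, P3, d) == pytest.approx(torsion, abs=1e-9)
        assert bond_angle(P2, P3, d) == pytest.approx(112.0, abs=1e-9)
        assert np.linalg.norm(d - P3) == pytest.approx(1.4, abs=1e-12)


class TestBuilder:
    @pytest.mark.parametrize("phi, psi", [(-62, -43), (-57, -47), (-49, -26), (-120, 120)])
    def test_torsion_round_trip(self, phi, psi):
        structure = build_peptide("A" * 12, [TorsionTriple(phi, psi, 180.0)] * 12)
        for t in backbone_torsions(structure.chains[0]):
            assert t.phi == pytest.approx(phi, abs=1e-6)
            assert t.psi == pytest.approx(psi, abs=1e-6)
            assert abs(t.omega) == pytest.approx(180.0, abs=1e-6)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-179, max_value=179),
                st.floats(min_value=-179, max_value=179),
            ),
            min_size=3,
            max_size=6,
        )
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_round_trip_arbitrary_torsions(self, pairs):
        torsions = [TorsionTriple(phi, psi, 180.0) for phi, psi in pairs]
        structure = build_peptide("A" * len(pairs), torsions)
        recovered = backbone_torsions(structure.chains[0])
        for given_t, got in zip(torsions, recovered):
            assert got.phi == pytest.approx(given_t.phi, abs=1e-6)
            assert got.psi == pytest.approx(given_t.psi, abs=1e-6)

    def test_trans_calpha_distance_matches_closed_form(self):
        # planar law-of-cosines chain over CA-C / C-N / N-CA with the
        # engh_huber angles gives 3.8040 A for omega = 180
        g = GEOMETRY_SETS["engh_huber"]
        expected = _ca_ca_distance(g, omega=180.0)
        assert expected == pytest.approx(3.804, abs=2e-3)
        structure = build_peptide("AA", [TorsionTriple(-62, -43, 180.0)] * 2)
        ca = [r.atoms["CA"].position for r in structure.chains[0].residues if "CA" in r.atoms]
        for a, b in zip(ca, ca[1:]):
            got = np.linalg.norm(np.subtract(a, b))
            assert got == pytest.approx(expected, abs=1e-9)

    def test_cis_calpha_distance_shorter(self):
        g = GEOMETRY_SETS["engh_huber"]
        expected_cis = _ca_ca_distance(g, omega=0.0)
        assert expected_cis == pytest.approx(2.771, abs=2e-3)
        structure = build_peptide(
            "AAA",
            [TorsionTriple(-62, -43, 180.0), TorsionTriple(-62, -43, 0.0), TorsionTriple(-62, -43, 180.0)],
        )
        ca = [r.atoms["CA"].position for r in structure.chains[0].residues if "CA" in r.atoms]
        d_cis = np.linalg.norm(np.subtract(ca[1], ca[0]))
        d_trans = np.linalg.norm(np.subtract(ca[2], ca[1]))
        assert d_cis == pytest.approx(expected_cis, abs=1e-9)
        assert d_cis < d_trans

    def test_unknown_residue_code_raises(self):
        with pytest.raises(ValueError, match="unknown residue code"):
            build_peptide(["XXX"], [TorsionTriple(-60, -45, 180.0)])

    def test_glycine_has_no_cb(self):
        structure = build_peptide("GAG", [TorsionTriple(-60, -45, 180.0)] * 3)
        residues = [r for r in structure.chains[0].residues if r.name in ("GLY", "ALA")]
        assert "CB" not in residues[0] and "CB" in residues[1] and "CB" not in residues[2]

    def test_caps_present_and_flagged(self, alpha_helix):
        names = [r.name for r in alpha_helix.chains[0].residues]
        assert names[0] == "ACE" and names[-1] == "NME"
        ace = alpha_helix.chains[0].residues[0]
        nme = alpha_helix.chains[0].residues[-1]
        assert "O" in ace and "H" not in ace       # acceptor-only
        assert "H" in nme and "O" not in nme       # donor-only

    def test_amide_planarity_at_trans(self, consensus_helix):
        residues = consensus_helix.chains[0].residues
        for prev, curr in zip(residues, residues[1:]):
            if "O" not in prev.atoms or "H" not in curr.atoms:
                continue
            improper = dihedral(
                prev.atoms["O"].position, prev.atoms["C"].position,
                curr.atoms["N"].position, curr.atoms["H"].position,
            )
            assert abs(improper) == pytest.approx(180.0, abs=1e-6)

    def test_torsions_invariant_under_rigid_motion(self, consensus_helix):
        import copy

        reference = backbone_torsions(consensus_helix.chains[0])
        rng = np.random.default_rng(42)
        for _ in range(3):
            rot = Rotation.random(rng=rng)
            shift = rng.normal(scale=20.0, size=3)
            moved = copy.deepcopy(consensus_helix)
            for _, residue in moved.iter_residues():
                for name, atom in residue.atoms.items():
                    residue.atoms[name] = type(atom)(
                        serial=atom.serial, name=atom.name, altloc=atom.altloc,
                        residue_name=atom.residue_name, chain_id=atom.chain_id,
                        residue_seq=atom.residue_seq, insertion_code=atom.insertion_code,
                        position=tuple(rot.apply(np.asarray(atom.position)) + shift),
                        occupancy=atom.occupancy, element=atom.element,
                    )
            for t_ref, t_new in zip(reference, backbone_torsions(moved.chains[0])):
                assert t_new.phi == pytest.approx(t_ref.phi, abs=1e-8)
                assert t_new.psi == pytest.approx(t_ref.psi, abs=1e-8)


def _ca_ca_distance(g, omega):
    """Independent closed-form CA-CA distance across one peptide bond."""
    c = np.zeros(2)
    n = np.array([g.c_n, 0.0])
    ang1 = math.radians(g.ang_ca_c_n)
    ca1 = g.ca_c * np.array([math.cos(ang1), math.sin(ang1)])
    ang2 = math.radians(180.0 - g.ang_c_n_ca)
    side = 1.0 if omega == 0.0 else -1.0
    ca2 = n + g.n_ca * np.array([math.cos(ang2), side * math.sin(ang2)])
    return float(np.linalg.norm(ca2 - ca1))


class TestTorsionExtraction:
    def test_first_residue_without_cap_has_no_phi(self):
        structure = build_peptide("AAAA", [TorsionTriple(-60, -45, 180.0)] * 4, caps=False)
        torsions = backbone_torsions(structure.chains[0])
        assert torsions[0].phi is None and torsions[0].omega is None
        assert torsions[-1].psi is None
        assert torsions[1].phi is not None

    def test_chain_break_undefines_flanking_torsions(self, consensus_helix):
        import copy

        broken = copy.deepcopy(consensus_helix)
        # translate residues 6.. away so C_5-N_6 stretches past the cutoff
        for residue in broken.chains[0].residues:
            if residue.seq >= 6:
                for name, atom in residue.atoms.items():
                    residue.atoms[name] = type(atom)(
                        serial=atom.serial, name=atom.name, altloc=atom.altloc,
                        residue_name=atom.residue_name, chain_id=atom.chain_id,
                        residue_seq=atom.residue_seq, insertion_code=atom.insertion_code,
                        position=tuple(np.asarray(atom.position) + [0.0, 0.0, 8.0]),
                        occupancy=atom.occupancy, element=atom.element,
                    )
        torsions = backbone_torsions(broken.chains[0])
        # residue 5 (index 4): psi needs N_6 -> undefined; residue 6: phi, omega undefined
        assert torsions[4].psi is None
        assert torsions[5].phi is None and torsions[5].omega is None
        assert torsions[3].psi is not None

    def test_missing_backbone_atom_undefines_not_raises(self, alpha_helix):
        import copy

        damaged = copy.deepcopy(alpha_helix)
        damaged.chains[0].residues[5].atoms.pop("CA")
        torsions = backbone_torsions(damaged.chains[0])
        assert torsions[4].phi is None  # residue 5's own angles gone
        assert torsions[0].phi is not None


class TestHydrogenPlacement:
    def test_nh_length_exact(self, alpha_helix):
        for _, residue in alpha_helix.iter_residues():
            if "H" in residue and "N" in residue:
                d = np.linalg.norm(
                    np.subtract(residue["H"].position, residue["N"].position)
                )
                assert d == pytest.approx(1.00, abs=1e-9)

    def test_h_in_amide_plane(self, alpha_helix):
        residues = alpha_helix.chains[0].residues
        for prev, curr in zip(residues, residues[1:]):
            if "H" not in curr or "C" not in prev:
                continue
            ca = curr.atoms.get("CA") or curr.atoms.get("CH3")
            n = np.asarray(curr["N"].position)
            normal = np.cross(
                np.asarray(prev["C"].position) - n, np.asarray(ca.position) - n
            )
            normal /= np.linalg.norm(normal)
            offset = abs(np.dot(np.asarray(curr["H"].position) - n, normal))
            assert offset < 1e-9

    def test_proline_receives_no_h(self):
        structure = build_peptide(
            "APA", [TorsionTriple(-60, -45, 180.0)] * 3, add_hydrogens=False
        )
        place_amide_hydrogens(structure)
        by_name = {r.seq: r for r in structure.chains[0].residues}
        assert "H" not in by_name[2]
        assert "H" in by_name[3]


class TestFixtureArchive:
    def test_demo_spec_round_trips_through_parser(self, fixture_archive):
        files = sorted(fixture_archive.glob("*.pdb"))
        assert len(files) == 5
        for path in files:
            structure = parse_pdb(path.read_text())
            assert structure.n_atoms > 0

    def test_assigned_resolution_survives(self, fixture_archive):
        structure = parse_pdb((fixture_archive / "alpha.pdb").read_text())
        assert structure.resolution == pytest.approx(1.2)

    def test_deterministic_output(self, tmp_path):
        spec = [("h1", (-62.0, -43.0), 1.1)]
        generate_fixture_archive(spec, tmp_path / "a")
        generate_fixture_archive(spec, tmp_path / "b")
        assert (tmp_path / "a/h1.pdb").read_bytes() == (tmp_path / "b/h1.pdb").read_bytes()

    def test_duplicate_labels_rejected(self, tmp_path):
        spec = [("x", (-60.0, -45.0), 1.0), ("x", (-50.0, -25.0), 2.0)]
        with pytest.raises(ValueError, match="duplicate"):
            generate_fixture_archive(spec, tmp_path)

    def test_empty_spec_is_fine(self, tmp_path):
        assert generate_fixture_archive([], tmp_path) == []

    def test_resolution_out_of_range_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="resolution"):
            generate_fixture_archive([("x", (-60.0, -45.0), 5.5)], tmp_path)
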