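"""PDB reading/writing, site resolution, reference distances and label
attachment."""

import numpy as np
import pytest

from labelsim.geometry import dihedral_deg, place_atom
from labelsim.structure import (
    AtomRecord,
    LabelSite,
    PDBFormatError,
    ProteinStructure,
    SiteClass,
    SiteResolutionError,
    attach_label,
    ca_distance,
    read_pdb,
    write_pdb,
)

from conftest import make_pdb_text


class TestReadPDB:
    def test_identity_read(self, two_atom_pdb):
        s = read_pdb(two_atom_pdb)
        assert len(s) == 2
        assert np.allclose(s.atoms[0].position, [1.234, 2.345, 3.456])
        assert np.allclose(s.atoms[1].position, [4.321, 5.432, 6.543])
        assert s.chains == {"A"}

    def test_multi_model_keeps_first(self, tmp_path):
        body1 = make_pdb_text([(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, 1.0, " ")])
        body2 = make_pdb_text([(1, "CA", "ALA", "A", 1, 9.0, 9.0, 9.0, 1.0, " ")])
        text = (
            "MODEL        1\n" + body1.replace("END\n", "ENDMDL\n")
            + "MODEL        2\n" + body2.replace("END\n", "ENDMDL\n") + "END\n"
        )
        path = tmp_path / "models.pdb"
        path.write_text(text)
        s = read_pdb(path)
        assert len(s) == 1
        assert np.allclose(s.atoms[0].position, [0.0, 0.0, 0.0])

    def test_altloc_highest_occupancy(self, tmp_path):
        """A (occ 0.6) vs B (occ 0.4): brute-force filtering of the raw
        records says only the A coordinates survive."""
        path = tmp_path / "altloc.pdb"
        path.write_text(
            make_pdb_text(
                [
                    (1, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0, 0.6, "A"),
                    (2, "CA", "ALA", "A", 1, 2.0, 0.0, 0.0, 0.4, "B"),
                ]
            )
        )
        s = read_pdb(path)
        assert len(s) == 1
        assert np.allclose(s.atoms[0].position, [1.0, 0.0, 0.0])
        assert s.atoms[0].occupancy == pytest.approx(0.6)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(PDBFormatError, match="not found"):
            read_pdb(tmp_path / "absent.pdb")

    def test_no_atoms_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(PDBFormatError, match="no ATOM records"):
            read_pdb(path)

    def test_round_trip_preserves_names_and_coordinates(self, helix_pair, tmp_path):
        structure, _ = helix_pair
        path = tmp_path / "helix.pdb"
        write_pdb(structure, path)
        back = read_pdb(path)
        assert len(back) == len(structure)
        assert [a.name for a in back.atoms] == [a.name for a in structure.atoms]
        # coordinates preserved to the printed precision (3 decimals)
        assert np.allclose(back.coordinates(), structure.coordinates(), atol=5e-4)


class TestCaDistance:
    def test_three_four_five(self):
        s = ProteinStructure(
            [
                AtomRecord("CA", "C", 1, "ALA", "A", [0.0, 0.0, 0.0]),
                AtomRecord("CA", "C", 2, "ALA", "A", [3.0, 4.0, 0.0]),
            ]
        )
        a, b = LabelSite("A", 1), LabelSite("A", 2)
        assert ca_distance(s, a, b) == pytest.approx(5.0)
        assert ca_distance(s, b, a) == pytest.approx(5.0)

    def test_adjacent_helix_residues_match_direct_arithmetic(self, helix_pair):
        structure, _ = helix_pair
        expected = float(
            np.linalg.norm(
                structure.atom("A", 10, "CA").position
                - structure.atom("A", 11, "CA").position
            )
        )
        assert ca_distance(
            structure, LabelSite("A", 10), LabelSite("A", 11)
        ) == pytest.approx(expected)
        # canonical helix rise: ~3.8 A between consecutive CA
        assert 3.6 < expected < 4.0

    def test_triangle_inequality(self, helix_pair):
        structure, _ = helix_pair
        sites = [LabelSite("A", i) for i in (3, 9, 17)]
        d01 = ca_distance(structure, sites[0], sites[1])
        d12 = ca_distance(structure, sites[1], sites[2])
        d02 = ca_distance(structure, sites[0], sites[2])
        assert d02 <= d01 + d12 + 1e-12

    def test_unresolvable_site(self, helix_pair):
        structure, _ = helix_pair
        with pytest.raises(SiteResolutionError):
            ca_distance(structure, LabelSite("A", 10), LabelSite("Z", 1))


class TestAttachLabel:
    def test_backbone_bit_identical(self, helix_pair, r1_template):
        structure, sites = helix_pair
        labeled, conformer = attach_label(
            structure, sites[0], r1_template, r1_template.reference_dihedrals
        )
        for name in ("N", "CA", "C"):
            for res in (9, 10, 11):
                orig = structure.atom("A", res, name).position
                new = labeled.atom("A", res, name).position
                assert np.array_equal(orig, new)
        assert labeled.atom("A", 10, "SG") is not None

    def test_label_residue_renamed(self, helix_pair, r1_template):
        structure, sites = helix_pair
        labeled, _ = attach_label(
            structure, sites[0], r1_template, r1_template.reference_dihedrals
        )
        res_atoms = labeled.residue_atoms("A", 10)
        assert all(a.residue_name == "R1A" for a in res_atoms)

    def test_glycine_cb_constructed(self, r1_template):
        """A residue without CB gets one at ideal geometry with the
        template bond length."""
        from labelsim.synthetic import _helix_backbone

        res = _helix_backbone(3)
        atoms = []
        for i, r in enumerate(res, start=1):
            for name, el in (("N", "N"), ("CA", "C"), ("C", "C")):
                atoms.append(AtomRecord(name, el, i, "GLY", "A", r[name]))
        s = ProteinStructure(atoms)
        labeled, _ = attach_label(
            s, LabelSite("A", 2), r1_template, r1_template.reference_dihedrals,
            clash_cutoff=None,
        )
        cb = labeled.atom("A", 2, "CB").position
        ca = labeled.atom("A", 2, "CA").position
        assert np.linalg.norm(cb - ca) == pytest.approx(1.53, abs=1e-9)

    def test_reporter_matches_internal_coordinate_oracle(
        self, helix_pair, r1_template
    ):
        """The reporter position for a given dihedral vector must match an
        independent chain-of-place_atom evaluation to < 1e-6 A."""
        structure, sites = helix_pair
        dihedrals = np.array([-65.0, 170.0, -75.0, 100.0, 10.0])
        _, conformer = attach_label(
            structure, sites[0], r1_template, dihedrals, clash_cutoff=None
        )
        # oracle: place every template atom sequentially by Z-matrix rules
        from labelsim.structure import resolve_site

        anchors = resolve_site(structure, sites[0])
        pos = dict(anchors)
        free = {key: dihedrals[i] for i, key in enumerate(r1_template.rotatable)}
        for spec in r1_template.atom_specs:
            dih = spec["dihedral"]
            if isinstance(dih, str):
                dih = free[dih]
            pos[spec["name"]] = place_atom(
                pos[spec["refs"][0]], pos[spec["refs"][1]], pos[spec["refs"][2]],
                spec["bond"], spec["angle"], dih,
            )
        oracle_reporter = 0.5 * (pos["N1"] + pos["O1"])
        assert np.linalg.norm(conformer.reporter - oracle_reporter) < 1e-6

    def test_clash_reported(self, helix_pair, r1_template):
        """A conformer driven into the second helix raises instead of
        being silently fixed."""
        structure, sites = helix_pair
        from labelsim.structure import StericClashError

        found = False
        for chi in np.arange(-180.0, 180.0, 30.0):
            try:
                attach_label(
                    structure, sites[0], r1_template,
                    [chi, 0.0, 0.0, 0.0, 0.0], clash_cutoff=3.0,
                )
            except StericClashError as exc:
                assert "clash" in str(exc)
                found = True
        assert found, "no orientation triggered the clash check"
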