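"""Topology file I/O: both dialects, round trips, coordinates, failures."""

import numpy as np
import pytest

import pertbuild as pb
from pertbuild import fixtures as fx
from pertbuild.core import ParseError, SerializationError


def _gro_text(names, xyz):
    lines = ["fixture", f" {len(names)}"]
    for i, (nm, x) in enumerate(zip(names, xyz), 1):
        lines.append("%5d%-5s%5s%5d%8.3f%8.3f%8.3f" % (1, "MOL", nm, i, *x))
    lines.append("   1.00000   1.00000   1.00000")
    return "\n".join(lines) + "\n"


class TestReadWrite:
    def test_gromos_ethane_counts(self, tmp_path, named):
        top, _ = named["ethane_ua"]
        p = tmp_path / "ethane.top"
        pb.write_topology(top, p, "gromos")
        back = pb.read_topology(p, "gromos")
        assert len(back.atoms) == 2 and len(back.bonds) == 1
        assert back.source_dialect == "gromos"

    def test_gromacs_methanol_counts(self, tmp_path, named):
        top, _ = named["methanol_ua"]
        p = tmp_path / "methanol.itp"
        pb.write_topology(top, p, "gromacs")
        back = pb.read_topology(p, "gromacs")
        assert (len(back.atoms), len(back.bonds), len(back.angles)) == (3, 2, 1)

    @pytest.mark.parametrize("dialect", ["gromos", "gromacs"])
    def test_round_trip_all_fixtures(self, tmp_path, named, dialect):
        for name, (top, _) in named.items():
            p = tmp_path / f"{name}.{dialect}"
            pb.write_topology(top, p, dialect)
            assert pb.semantically_equal(top, pb.read_topology(p, dialect)), \
                f"round trip changed {name} in {dialect}"

    def test_cross_dialect_preserves_content(self, tmp_path, named):
        for name, (top, _) in named.items():
            p1 = tmp_path / f"{name}.g"
            pb.write_topology(top, p1, "gromos")
            mid = pb.read_topology(p1, "gromos")
            p2 = tmp_path / f"{name}.x"
            pb.write_topology(mid, p2, "gromacs")
            back = pb.read_topology(p2, "gromacs")
            assert pb.semantically_equal(top, back), name
            assert [a.mass for a in back.atoms] == [a.mass for a in top.atoms]
            assert back.bond_set() == top.bond_set()

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOError):
            pb.read_topology(tmp_path / "absent.top", "gromos")

    def test_dangling_bond_index_rejected(self, tmp_path, named):
        top, _ = named["ethane_ua"]
        p = tmp_path / "bad.top"
        pb.write_topology(top, p, "gromos")
        text = p.read_text().replace("1 2 1", "1 3 1")
        p.write_text(text)
        with pytest.raises(ParseError):
            pb.read_topology(p, "gromos")

    def test_unknown_block_rejected(self, tmp_path, named):
        top, _ = named["ethane_ua"]
        p = tmp_path / "bad.top"
        pb.write_topology(top, p, "gromos")
        p.write_text(p.read_text() + "\nNOSUCHBLOCK\n1\nEND\n")
        with pytest.raises(ParseError):
            pb.read_topology(p, "gromos")

    def test_unknown_gromacs_section_rejected(self, tmp_path, named):
        top, _ = named["ethane_ua"]
        p = tmp_path / "bad.itp"
        pb.write_topology(top, p, "gromacs")
        p.write_text(p.read_text() + "\n[ nonsense ]\n1 2\n")
        with pytest.raises(ParseError):
            pb.read_topology(p, "gromacs")

    def test_required_line_removed_breaks_parse(self, tmp_path, named):
        """Fuzz: deleting any SOLUTEATOM line must be caught."""
        top, _ = named["methanol_ua"]
        p = tmp_path / "m.top"
        pb.write_topology(top, p, "gromos")
        lines = p.read_text().splitlines()
        idx = next(i for i, l in enumerate(lines) if l.startswith("2 1 O"))
        p.write_text("\n".join(lines[:idx] + lines[idx + 1:]))
        with pytest.raises(ParseError):
            pb.read_topology(p, "gromos")

    def test_unresolvable_param_ref_rejected_on_write(self, tmp_path, named):
        top, _ = fx.make_fixture("ethane_ua")
        top.bonds[0] = (0, 1, "nosuchref")
        with pytest.raises(pb.TopologyError):
            pb.write_topology(top, tmp_path / "x.top", "gromos")

    def test_gromos_needs_charge_groups(self, tmp_path, named):
        top, _ = fx.make_fixture("ethane_ua")
        for a in top.atoms:
            a.charge_group = None
        with pytest.raises(SerializationError):
            pb.write_topology(top, tmp_path / "x.top", "gromos")


class TestIncludeHandling:
    def test_include_is_inlined(self, tmp_path, named):
        top, _ = named["methanol_ua"]
        full = tmp_path / "mol.itp"
        pb.write_topology(top, full, "gromacs")
        text = full.read_text()
        head, _, tail = text.partition("[ bonds ]")
        (tmp_path / "bonded.itp").write_text("[ bonds ]" + tail)
        full.write_text(head + '#include "bonded.itp"\n')
        back = pb.read_topology(full, "gromacs")
        assert pb.semantically_equal(top, back)

    def test_unresolved_include_is_an_error(self, tmp_path):
        p = tmp_path / "mol.itp"
        p.write_text('#include "missing.itp"\n')
        with pytest.raises(ParseError, match="include"):
            pb.read_topology(p, "gromacs")

    def test_define_macro_substitution(self, tmp_path):
        p = tmp_path / "mol.itp"
        p.write_text(
            "#define GB_CC 0.153 334720.0\n"
            "[ moleculetype ]\nethane 0\n[ atoms ]\n"
            "1 CH3 1 MOL C1 1 0.0 15.035\n2 CH3 1 MOL C2 2 0.0 15.035\n"
            "[ bonds ]\n1 2 1 GB_CC\n")
        top = pb.read_topology(p, "gromacs")
        assert top.resolve(top.bonds[0][2]) == (0.153, 334720.0)


class TestCoordinates:
    def test_gro_positions_in_nm(self, tmp_path):
        p = tmp_path / "m.gro"
        p.write_text(_gro_text(["C1", "O", "H"],
                               [(0, 0, 0), (0.144, 0, 0), (0.176, 0.092, 0)]))
        c = pb.read_coordinates(p)
        assert len(c) == 3
        np.testing.assert_allclose(c.positions[1], [0.144, 0, 0], atol=1e-5)

    def test_pdb_angstrom_converted(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(
            "ATOM      1  C1  MOL A   1       0.000   0.000   0.000  1.00  0.00\n"
            "ATOM      2  O   MOL A   1       1.440   0.000   0.000  1.00  0.00\n"
            "END\n")
        c = pb.read_coordinates(p)
        np.testing.assert_allclose(c.positions[1], [0.144, 0, 0], atol=1e-6)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.gro"
        p.write_text("")
        with pytest.raises(ParseError):
            pb.read_coordinates(p)

    def test_atom_count_mismatch_detected(self, tmp_path, named):
        top, _ = named["methanol_ua"]
        p = tmp_path / "m.gro"
        p.write_text(_gro_text(["C1", "C2"], [(0, 0, 0), (0.15, 0, 0)]))
        c = pb.read_coordinates(p)
        with pytest.raises(pb.TopologyError):
            c.validate_against(top)
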