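import numpy as np
import pytest

from tagsite import (
    DsspRecord,
    load_max_sasa_table,
    parse_dssp,
    parse_structure,
    rsa_track,
    shrake_rupley_sasa,
    ss_track,
    validate_sequence,
)
from tagsite.structure import (
    SS_SCORES,
    StructureError,
    canonicalize_ss_code,
    map_structure_to_query,
    sasa_from_dssp,
    ss_from_structure,
)
from tagsite.synthetic import _write_backbone_pdb

# Van der Waals radii of the "Single" element set used by the implementation.
_VDW = {"N": 1.55, "C": 1.7, "O": 1.52, "S": 1.8, "H": 1.2}


def brute_force_sasa(atoms, probe=1.4, n_points=2000, seed=7):
    """Independent Monte-Carlo Shrake-Rupley: random sphere points per atom,
    count those outside every other solvated sphere."""
    rng = np.random.default_rng(seed)
    coords = atoms.coord
    radii = np.array([_VDW[e] for e in atoms.element]) + probe
    per_atom = np.zeros(len(radii))
    for i in range(len(radii)):
        direction = rng.normal(size=(n_points, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        points = coords[i] + radii[i] * direction
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(radii)):
            if j == i:
                continue
            exposed &= np.linalg.norm(points - coords[j], axis=1) >= radii[j]
        per_atom[i] = 4 * np.pi * radii[i] ** 2 * exposed.mean()
    return per_atom


class TestParseStructure:
    def test_toy_pdb(self, tmp_path):
        path = tmp_path / "toy.pdb"
        _write_backbone_pdb(path, "ACD", np.zeros(3, dtype=bool))
        model = parse_structure(path)
        assert model.n_residues == 3
        assert model.sequence == "ACD"
        assert np.isfinite(model.atoms.coord).all()

    def test_b_factor_read_as_plddt(self, bundle):
        model = parse_structure(bundle.pdb)
        assert model.plddt is not None
        assert model.plddt.min() >= 0 and model.plddt.max() <= 100
        # planted window carries lower model confidence
        assert model.plddt[bundle.peak_position - 1] < model.plddt[0]

    def test_hetatm_only_file_rejected(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1      10.000  10.000  10.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(StructureError, match="no protein residues"):
            parse_structure(path)

    def test_multichain_requires_selector(self, tmp_path):
        path = tmp_path / "two_chains.pdb"
        lines = []
        for i, chain in enumerate("AB"):
            lines.append(
                f"ATOM  {i * 2 + 1:>5}  N   ALA {chain}   1    "
                f"{10.0 * i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 50.00           N\n"
            )
            lines.append(
                f"ATOM  {i * 2 + 2:>5}  CA  ALA {chain}   1    "
                f"{10.0 * i + 1.5:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00 50.00           C\n"
            )
        path.write_text("".join(lines) + "END\n")
        with pytest.raises(StructureError, match="chain"):
            parse_structure(path)
        model = parse_structure(path, chain="B")
        assert model.n_residues == 1


class TestParseDssp:
    def test_fixture_file(self, bundle, bundle_query):
        records = parse_dssp(bundle.dssp)
        assert len(records) == bundle_query.length
        codes = {r.ss_code for r in records}
        assert codes == {"H", "C"}
        in_window = [r for r in records if r.position in bundle.window_positions]
        assert all(r.ss_code == "C" for r in in_window)

    def test_blank_ss_canonicalizes_to_coil(self):
        assert canonicalize_ss_code(" ") == "C"
        assert canonicalize_ss_code("-") == "C"

    def test_unknown_code_named_in_error(self):
        with pytest.raises(StructureError, match="'Z'"):
            canonicalize_ss_code("Z")

    def test_mmcif_dialect(self, tmp_path):
        path = tmp_path / "toy_dssp.cif"
        path.write_text(
            "data_test\n"
            "loop_\n"
            "_dssp_struct_summary.label_comp_id\n"
            "_dssp_struct_summary.label_seq_id\n"
            "_dssp_struct_summary.secondary_structure\n"
            "_dssp_struct_summary.accessibility\n"
            "ALA 1 H 10.0\n"
            "GLY 2 . 50.0\n"
        )
        records = parse_dssp(path)
        assert [(r.position, r.ss_code, r.sasa) for r in records] == [
            (1, "H", 10.0),
            (2, "C", 50.0),
        ]

    def test_no_residue_lines(self, tmp_path):
        path = tmp_path / "empty.dssp"
        path.write_text("==== nothing ====\n  #  RESIDUE AA\n")
        with pytest.raises(StructureError, match="no residue lines"):
            parse_dssp(path)


class TestSsTrack:
    def test_full_alphabet_binning(self):
        query = validate_sequence("A" * 9)
        codes = list("HGIEBTSPC")
        track = ss_track(codes, query)
        expected = [0, 0, 0, 0, 0.5, 0.5, 0.5, 0.5, 1.0]
        np.testing.assert_array_equal(track.values, expected)
        assert set(np.unique(track.values)) <= {0.0, 0.5, 1.0}

    def test_records_with_missing_positions(self):
        query = validate_sequence("AAAA")
        records = [DsspRecord(1, "A", "H", 5.0), DsspRecord(3, "A", "C", 5.0)]
        track = ss_track(records, query)
        assert track.values[0] == 0.0 and track.values[2] == 1.0
        assert np.isnan(track.values[1]) and np.isnan(track.values[3])

    def test_out_of_range_position_rejected(self):
        query = validate_sequence("AA")
        with pytest.raises(StructureError, match="position 5"):
            ss_track([DsspRecord(5, "A", "C", 1.0)], query)


class TestRsaTrack:
    def test_identity_and_clamping(self):
        table = load_max_sasa_table()
        query = validate_sequence("AAAX")
        sasa = [0.0, table["A"], 1.2 * table["A"], 50.0]
        track = rsa_track(sasa, query, table)
        np.testing.assert_allclose(track.values[:3], [0.0, 1.0, 1.0])
        assert np.isnan(track.values[3])  # X: no max-SA value

    def test_monotone_before_clamp(self):
        query = validate_sequence("AAAA")
        increasing = rsa_track([10, 20, 40, 80], query).values
        assert (np.diff(increasing) > 0).all()

    def test_table_complete(self):
        table = load_max_sasa_table()
        assert len(table) == 20
        assert all(v > 0 for v in table.values())


class TestShrakeRupley:
    def test_matches_independent_monte_carlo(self, tmp_path):
        path = tmp_path / "penta.pdb"
        _write_backbone_pdb(path, "ACDEF", np.zeros(5, dtype=bool))
        model = parse_structure(path)
        sasa = shrake_rupley_sasa(model, n_points=1000)
        import biotite.structure as struc

        oracle_atoms = brute_force_sasa(model.atoms)
        oracle = struc.apply_residue_wise(model.atoms, oracle_atoms, np.nansum)
        np.testing.assert_allclose(sasa, oracle, rtol=0.10)

    def test_buried_atom_has_zero_sasa(self, tmp_path):
        # central atom caged by a dense shell of atoms: zero exposure
        import biotite.structure as struc

        n_shell = 60
        atoms = struc.AtomArray(n_shell + 1)
        coords = np.zeros((n_shell + 1, 3))
        golden = np.pi * (3 - np.sqrt(5))
        for k in range(n_shell):
            z = 1 - 2 * (k + 0.5) / n_shell
            r = np.sqrt(1 - z * z)
            coords[k + 1] = 3.0 * np.array(
                [r * np.cos(golden * k), r * np.sin(golden * k), z]
            )
        atoms.coord = coords
        atoms.chain_id[:] = "A"
        atoms.res_id[:] = 1
        atoms.res_name[:] = "ALA"
        atoms.atom_name[:] = "C"
        atoms.element[:] = "C"
        atoms.hetero[:] = False
        per_atom = struc.sasa(
            atoms, probe_radius=1.4, point_number=500, vdw_radii="Single"
        )
        assert per_atom[0] == pytest.approx(0.0, abs=1e-9)

    def test_point_count_convergence(self, tmp_path):
        path = tmp_path / "tri.pdb"
        _write_backbone_pdb(path, "ACD", np.zeros(3, dtype=bool))
        model = parse_structure(path)
        coarse = shrake_rupley_sasa(model, n_points=960)
        fine = shrake_rupley_sasa(model, n_points=1920)
        np.testing.assert_allclose(coarse, fine, rtol=0.02)

    def test_deterministic(self, tmp_path):
        path = tmp_path / "tri.pdb"
        _write_backbone_pdb(path, "ACD", np.zeros(3, dtype=bool))
        model = parse_structure(path)
        np.testing.assert_array_equal(
            shrake_rupley_sasa(model), shrake_rupley_sasa(model)
        )


class TestSequenceStructureMapping:
    def test_identity(self, bundle, bundle_query):
        model = parse_structure(bundle.pdb)
        mapping = map_structure_to_query(model, bundle_query)
        np.testing.assert_array_equal(mapping, np.arange(bundle_query.length))

    def test_mismatch_names_first_position(self, tmp_path):
        path = tmp_path / "mm.pdb"
        _write_backbone_pdb(path, "AAAAGAAAAA", np.zeros(10, dtype=bool))
        query = validate_sequence("AAAAAAAAAA")
        model = parse_structure(path)
        with pytest.raises(StructureError, match="position 5"):
            map_structure_to_query(model, query)

    def test_missing_residues_map_to_minus_one(self, tmp_path):
        path = tmp_path / "trunc.pdb"
        _write_backbone_pdb(path, "ACDEF", np.zeros(5, dtype=bool))
        query = validate_sequence("ACDEFGH")
        model = parse_structure(path)
        mapping = map_structure_to_query(model, query)
        np.testing.assert_array_equal(mapping[:5], np.arange(5))
        assert (mapping[5:] == -1).all()


def test_sasa_from_dssp_cross_checks_residues(bundle, bundle_query):
    records = parse_dssp(bundle.dssp)
    sasa = sasa_from_dssp(records, bundle_query)
    assert np.isfinite(sasa).all()
    bad = [DsspRecord(1, "W" if bundle_query.sequence[0] != "W" else "A", "C", 5.0)]
    with pytest.raises(StructureError, match="position 1"):
        sasa_from_dssp(bad, bundle_query)


def test_ss_from_structure_is_coil_heavy_on_extended_backbone(bundle):
    model = parse_structure(bundle.pdb)
    codes = ss_from_structure(model)
    assert len(codes) == model.n_residues
    assert set(codes) <= set(SS_SCORES)
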