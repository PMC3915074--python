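"""Format detection, dialect parsing, executable names, sequences."""

import pytest

from simmeta import (
    detect_format,
    generate_md_study,
    generate_qm_study,
    load_study_directory,
    normalize_sequence,
    parse_executable_name,
    parse_md_output,
    parse_qm_output,
    parse_topology,
)
from simmeta.errors import ParseError, UsageError

PDB_SNIPPET = (
    "HEADER    NUCLEIC ACID\n"
    "ATOM      1  O5'   G A   1      1.0  2.0  3.0  1.00  0.00\n"
)

TOPOLOGY = """%SIMTOP 1.0
%SECTION SYSTEM
NAME = water box
MOLECULE_TYPES = 1
%SECTION MOLECULE
NAME = WAT
COUNT = 216
TYPE = solvent
N_RESIDUES = 1
RESIDUES = WAT
ATOMS = H:2,O:1
"""

MDLOG = """%MDLOG 1.0
TASK_KIND = md
RUN_CONTEXT = production
THERMOSTAT = Nose-Hoover
N_STEPS = 1000
FOOTER: COMPLETE
"""


class TestDetectFormat:
    @pytest.mark.parametrize("text,expected", [
        (PDB_SNIPPET, "PDB"),
        (TOPOLOGY, "SIMTOP"),
        (MDLOG, "MDLOG"),
        ("%QMLOG 1.0\nMETHOD = HF\n", "QMLOG"),
        ("%TRAJ segment 1\n", "TRAJ"),
        ("\n", "unknown"),
        ("random text\nwith lines\n", "unknown"),
    ])
    def test_content_based_detection(self, text, expected):
        assert detect_format(text) == expected

    def test_empty_file_is_unknown(self, tmp_path):
        path = tmp_path / "empty.dat"
        path.touch()
        assert detect_format(path) == "unknown"


class TestParseMDOutput:
    def test_declared_thermostat_lands_in_parameter_fragment(self):
        record = parse_md_output(MDLOG)
        assert record.parameters.thermostat.implementation_name == "Nose-Hoover"
        assert record.parameters.n_steps == 1000

    def test_missing_footer_means_incomplete(self):
        record = parse_md_output("%MDLOG 1.0\nTASK_KIND = md\n")
        assert record.execution.termination_status == "incomplete"

    def test_absent_keys_yield_absent_fields(self):
        record = parse_md_output("%MDLOG 1.0\nTASK_KIND = md\nFOOTER: OK\n")
        assert record.parameters.thermostat is None
        assert record.parameters.n_steps is None
        assert record.conditions is None
        assert record.software is None

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ParseError, match="line 3"):
            parse_md_output("%MDLOG 1.0\nTASK_KIND = md\nBOGUS LINE\n")

    def test_generated_output_matches_manifest_record(self, tmp_path):
        manifest = generate_md_study(tmp_path / "s", seed=1)
        record = parse_md_output(manifest.records[0].source_file.path)
        assert record == manifest.records[0]


class TestParseTopology:
    def test_water_block_gives_h2_o1_occurrences(self):
        system = parse_topology(TOPOLOGY)
        water = system.molecules[0]
        counts = {a.element: a.count for a in water.atom_occurrences}
        assert counts == {"H": 2, "O": 1}
        assert water.count == 216

    def test_explicit_solvent_keeps_water_definition_and_count(self, tmp_path):
        manifest = generate_md_study(tmp_path / "s", seed=2)
        system = parse_topology(manifest.system.topology_files[0].path)
        water = next(m for m in system.molecules if m.name == "WAT")
        assert water.count == next(
            m.count for m in manifest.system.molecules if m.name == "WAT")
        assert {a.element: a.count for a in water.atom_occurrences} == {
            "H": 2, "O": 1}

    def test_generated_topology_matches_manifest_system(self, tmp_path):
        manifest = generate_md_study(tmp_path / "s", seed=2)
        assert parse_topology(
            manifest.system.topology_files[0].path) == manifest.system

    def test_inconsistent_declared_count_is_a_parse_error(self):
        bad = TOPOLOGY.replace("MOLECULE_TYPES = 1", "MOLECULE_TYPES = 3")
        with pytest.raises(ParseError, match="3 molecule types"):
            parse_topology(bad)

    def test_inconsistent_residue_count_is_a_parse_error(self):
        bad = TOPOLOGY.replace("N_RESIDUES = 1", "N_RESIDUES = 5")
        with pytest.raises(ParseError):
            parse_topology(bad)


class TestParseQMOutput:
    def test_unmapped_basis_set_name_is_retained(self):
        record = parse_qm_output(
            "%QMLOG 1.0\nMETHOD = MP2\nBASIS_SET = LANL2DZ\nFOOTER: OK\n")
        assert record.parameters.basis_set_name == "LANL2DZ"
        assert record.parameters.method.specific_name == "MP2"

    def test_malformed_header_is_a_parse_error(self):
        with pytest.raises(ParseError):
            parse_qm_output("METHOD = MP2\n")

    def test_generated_output_matches_manifest_record(self, tmp_path):
        manifest = generate_qm_study(tmp_path / "q", seed=3)
        record = parse_qm_output(manifest.records[0].source_file.path)
        assert record == manifest.records[0]


class TestExecutableNames:
    def test_gaussian_build_string_splits_into_parts(self):
        info = parse_executable_name("EM64L-G09RevC.01")
        assert (info.product, info.revision, info.target_architecture) == (
            "G09", "C.01", "EM64L")
        assert info.raw == "EM64L-G09RevC.01"

    def test_known_engine_executable_maps_to_product(self):
        info = parse_executable_name("SANDER")
        assert info.product == "SANDER"
        assert info.revision is None

    def test_unrecognized_name_degrades_to_raw(self):
        info = parse_executable_name("mystery-binary")
        assert info.raw == "mystery-binary"
        assert info.product is None and info.revision is None


class TestNormalizeSequence:
    @pytest.mark.parametrize("residues,expected", [
        (["ALA", "GLY", "SER"], "AGS"),
        (["DA", "DT", "DG", "DC"], "ATGC"),
        (["ALA", "LIGX"], "AX"),
        (["WAT"], "X"),
    ])
    def test_one_letter_codes(self, residues, expected):
        assert normalize_sequence(residues) == expected

    def test_output_length_equals_residue_count(self, dictionaries):
        residues = ["ALA", "DA", "NOPE", "TRP", "U", "WAT", "HIS"]
        assert len(normalize_sequence(residues,
                                      dictionaries["residue"])) == len(residues)

    def test_empty_list_is_a_usage_error(self):
        with pytest.raises(UsageError):
            normalize_sequence([])


def test_parsers_never_invent_values(tmp_path):
    """Every field of every parsed record round-trips the generator manifest
    exactly — nothing defaulted, nothing dropped."""
    for seed in (1, 5, 9):
        manifest = generate_md_study(tmp_path / f"s{seed}", seed=seed)
        systems, records, _ = load_study_directory(manifest.directory)
        assert systems == [manifest.system]
        assert records == manifest.records
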