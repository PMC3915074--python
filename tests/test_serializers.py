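"""XML round trips, HTML rendering, and relational DDL generation."""

import sqlite3

import pytest
from lxml import etree

from simmeta import (
    assemble_directory,
    attach_extended_attribute,
    default_model_descriptor,
    from_xml,
    generate_ddl,
    generate_md_study,
    generate_qm_study,
    generate_remd_study,
    load_dictionaries_into,
    render_html,
    to_xml,
    to_xml_string,
)
from simmeta.errors import SchemaError, SerializationError
from simmeta.fixtures import MDStudyConfig
from simmeta.model import Experiment
from simmeta.serializers import count_entity_nodes, validate_document
from simmeta.serializers.ddl import EntityDescriptor, ModelDescriptor


class TestXMLRoundTrip:
    def test_empty_experiment_is_a_single_root_element(self):
        tree = to_xml(Experiment(id="e0", name="empty"))
        root = tree.getroot()
        assert root.tag == "experiment"
        assert (root.get("id"), root.get("name")) == ("e0", "empty")
        assert len(root) == 0

    def test_md_study_document_nests_min_and_md_tasks(self, md_experiment):
        root = to_xml(md_experiment).getroot()
        kinds = [el.get("kind") for el in root.iter("task")]
        assert kinds == ["minimization", "md", "md"]
        assert root.find("processGroup/process/task/mdParameterSet") is not None

    @pytest.mark.parametrize("maker,seed", [
        ("md", 21), ("md", 22), ("remd", 23), ("qm", 24)])
    def test_round_trip_is_identity(self, tmp_path, maker, seed):
        if maker == "md":
            manifest = generate_md_study(tmp_path / "s", seed=seed)
        elif maker == "remd":
            manifest = generate_remd_study(tmp_path / "s", seed=seed,
                                           n_replicas=3)
        else:
            manifest = generate_qm_study(tmp_path / "s", seed=seed)
        experiment = assemble_directory(manifest.directory)
        assert from_xml(to_xml(experiment)) == experiment

    def test_round_trip_preserves_extended_attributes_and_dependencies(
            self, tmp_path):
        manifest = generate_md_study(tmp_path / "s", seed=31)
        experiment = assemble_directory(manifest.directory)
        task = next(experiment.all_tasks())
        attach_extended_attribute(task.md_parameters,
                                  "PME interpolation order", "4")
        attach_extended_attribute(experiment, "lab id", "X-17", unit=None,
                                  concept_id="C123")
        restored = from_xml(to_xml(experiment))
        assert restored == experiment
        restored_task = next(restored.all_tasks())
        assert restored_task.md_parameters.extended[0].attribute == \
            "PME interpolation order"
        assert [t.depends_on for t in restored.all_tasks()] == \
            [t.depends_on for t in experiment.all_tasks()]

    def test_invalid_experiment_is_refused_with_report(self):
        experiment = Experiment(id="e", name="broken")
        from simmeta.model import Process, ProcessGroup, MDTask
        task = MDTask(id="t")
        group = ProcessGroup(id="g", processes=[Process(id="p", tasks=[task])])
        experiment.process_groups = [group]
        with pytest.raises(SerializationError, match="no molecular system"):
            to_xml(experiment)

    def test_unknown_extra_element_is_rejected_with_path(self, md_experiment):
        root = to_xml(md_experiment).getroot()
        etree.SubElement(root, "surprise")
        with pytest.raises(SerializationError, match="surprise"):
            from_xml(root)

    def test_schema_validates_generated_documents(self, md_experiment):
        validate_document(to_xml(md_experiment))  # must not raise


class TestRenderHTML:
    def test_empty_experiment_renders_single_root_node(self):
        page = render_html(Experiment(id="e0", name="empty"))
        parsed = etree.fromstring(page.split("\n", 1)[1])
        details = parsed.findall(".//details")
        assert len(details) == 1
        assert details[0].get("data-kind") == "experiment"

    def test_three_process_fixture_renders_three_process_nodes(
            self, md_experiment):
        page = render_html(md_experiment)
        parsed = etree.fromstring(page.split("\n", 1)[1])
        processes = [d for d in parsed.findall(".//details")
                     if d.get("data-kind") == "process"]
        assert len(processes) == 3

    def test_markup_is_well_formed_and_loses_no_entities(self, tmp_path):
        manifest = generate_remd_study(tmp_path / "r", seed=41, n_replicas=2)
        experiment = assemble_directory(manifest.directory)
        page = render_html(experiment)
        parsed = etree.fromstring(page.split("\n", 1)[1])  # parse = well-formed
        nodes = parsed.findall(".//details")
        assert len(nodes) == count_entity_nodes(experiment)


class TestGenerateDDL:
    def test_dictionary_link_column_becomes_foreign_key(self, dictionaries):
        ddl = generate_ddl(default_model_descriptor(dictionaries))
        create = next(s for s in ddl.split("\n\n")
                      if s.startswith("CREATE TABLE force_field "))
        assert "FOREIGN KEY (type_id) REFERENCES force_field_type (id)" in create

    def test_entities_get_companion_extension_tables(self, dictionaries):
        ddl = generate_ddl(default_model_descriptor(dictionaries))
        assert "CREATE TABLE md_parameter_set_extended_attribute" in ddl
        assert "CREATE TABLE experiment_task_extended_attribute" in ddl

    def test_dangling_entity_link_is_a_generation_error(self, dictionaries):
        descriptor = ModelDescriptor(
            entities=[EntityDescriptor("widget", [("name", "TEXT")],
                                       links=[("gadget_id", "gadget")])],
            dictionaries=dictionaries)
        with pytest.raises(SchemaError, match="gadget"):
            generate_ddl(descriptor)

    def test_script_executes_and_accepts_every_dictionary_row(
            self, dictionaries):
        ddl = generate_ddl(default_model_descriptor(dictionaries))
        connection = sqlite3.connect(":memory:")
        connection.executescript(ddl)
        rows = load_dictionaries_into(connection, dictionaries)
        expected = sum(len(d) for d in dictionaries.values())
        assert rows == expected
        stored = connection.execute(
            "SELECT COUNT(*) FROM force_field").fetchone()[0]
        assert stored == len(dictionaries["force_field"])
        connection.close()

    def test_script_is_idempotent_under_drop_and_recreate(self, dictionaries):
        ddl = generate_ddl(default_model_descriptor(dictionaries))
        connection = sqlite3.connect(":memory:")
        connection.executescript(ddl)
        load_dictionaries_into(connection, dictionaries)
        connection.executescript(ddl)  # drops and recreates cleanly
        rows = load_dictionaries_into(connection, dictionaries)
        assert rows == sum(len(d) for d in dictionaries.values())
        connection.close()


def test_xml_string_output_is_parseable(md_experiment):
    text = to_xml_string(md_experiment)
    assert etree.fromstring(text.encode()).tag == "experiment"
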