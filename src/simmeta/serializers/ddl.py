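"""Generate relational DDL for the model entities and dictionaries.

One table per entity and per dictionary; foreign-key constraints for
links; a companion ``<table>_extended_attribute`` table per entity that
carries extended attributes (the relationally sound alternative to a
single global triplet table).  The baseline dialect is portable SQL that
an embedded engine (sqlite3) executes directly; the dialect name is a
generation flag so engine-specific variants can hang off the same
descriptor.  Scripts are idempotent: each table is dropped before it is
recreated.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field

from ..dictionaries import Dictionary, DictionarySet
from ..errors import SchemaError


@dataclass
class EntityDescriptor:
    """One model entity to map to a table."""

    name: str
    fields: list[tuple[str, str]]  # (column, SQL type), id column implied
    links: list[tuple[str, str]] = field(default_factory=list)  # (column, target table)
    extended: bool = True


@dataclass
class ModelDescriptor:
    entities: list[EntityDescriptor]
    dictionaries: DictionarySet = field(default_factory=dict)


#: The model entities, their scalar columns and their containment links.
_MODEL_ENTITIES: list[EntityDescriptor] = [
    EntityDescriptor("experiment", [
        ("name", "TEXT"), ("role", "TEXT")]),
    EntityDescriptor("author", [
        ("name", "TEXT"), ("institution", "TEXT"), ("contact", "TEXT"),
    ], links=[("experiment_id", "experiment")], extended=False),
    EntityDescriptor("citation", [
        ("text", "TEXT")], links=[("experiment_id", "experiment")],
        extended=False),
    # "grant" is an SQL keyword; the table gets a safe name
    EntityDescriptor("grant_info", [
        ("agency", "TEXT"), ("number", "TEXT")],
        links=[("experiment_id", "experiment")], extended=False),
    EntityDescriptor("molecular_system", [("name", "TEXT")]),
    EntityDescriptor("molecule", [
        ("name", "TEXT"), ("count", "INTEGER"), ("molecule_type", "TEXT"),
        ("specific_chain", "TEXT"), ("normalized_chain", "TEXT"),
    ], links=[("system_id", "molecular_system")]),
    EntityDescriptor("residue_occurrence", [
        ("name", "TEXT"), ("count", "INTEGER"), ("specific_symbol", "TEXT"),
    ], links=[("molecule_id", "molecule"), ("residue_id", "residue")],
        extended=False),
    EntityDescriptor("atom_occurrence", [
        ("count", "INTEGER"), ("specific_symbol", "TEXT"),
    ], links=[("molecule_id", "molecule"), ("element_id", "element")],
        extended=False),
    EntityDescriptor("process_group", [],
                     links=[("experiment_id", "experiment"),
                            ("system_id", "molecular_system")]),
    EntityDescriptor("process", [],
                     links=[("process_group_id", "process_group")]),
    EntityDescriptor("md_parameter_set", [
        ("ensemble", "TEXT"), ("electrostatics_model", "TEXT"),
        ("n_steps", "INTEGER"), ("step_length", "REAL"),
        ("step_length_unit", "TEXT"), ("collision_frequency", "REAL"),
        ("collision_frequency_unit", "TEXT"),
        ("barostat_name", "TEXT"), ("thermostat_name", "TEXT"),
    ], links=[("barostat_id", "barostat"), ("thermostat_id", "thermostat"),
              ("ensemble_id", "ensemble"),
              ("electrostatics_id", "electrostatics")]),
    EntityDescriptor("qm_parameter_set", [
        ("method_name", "TEXT"), ("basis_set_name", "TEXT"),
        ("frozen_core", "INTEGER"), ("pseudopotentials", "INTEGER"),
        ("plane_wave_cutoff", "REAL"), ("plane_wave_cutoff_unit", "TEXT"),
        ("convergence_flag", "INTEGER"), ("convergence_criteria", "TEXT"),
    ], links=[("method_id", "qm_method"), ("basis_set_id", "basis_set")]),
    EntityDescriptor("qmmm_parameter_set", [
        ("boundary_treatment", "TEXT")]),
    EntityDescriptor("force_field_instance", [
        ("specific_name", "TEXT")],
        links=[("md_parameter_set_id", "md_parameter_set"),
               ("definition_id", "force_field")], extended=False),
    EntityDescriptor("experiment_task", [
        ("kind", "TEXT"), ("method_name", "TEXT"), ("description", "TEXT"),
        ("boundary_conditions", "TEXT"), ("solvent_type", "TEXT"),
        ("reference_pressure", "REAL"), ("reference_pressure_unit", "TEXT"),
        ("reference_temperature", "REAL"),
        ("reference_temperature_unit", "TEXT"),
        ("os", "TEXT"), ("cpu_architecture", "TEXT"),
        ("gpu_architecture", "TEXT"), ("machine_architecture", "TEXT"),
        ("machine_name", "TEXT"),
        ("software_name", "TEXT"), ("software_version", "TEXT"),
        ("executable", "TEXT"),
        ("start_time", "TEXT"), ("end_time", "TEXT"),
        ("elapsed_seconds", "REAL"), ("termination_status", "TEXT"),
    ], links=[("process_id", "process"),
              ("md_parameter_set_id", "md_parameter_set"),
              ("qm_parameter_set_id", "qm_parameter_set"),
              ("qmmm_parameter_set_id", "qmmm_parameter_set"),
              ("software_id", "software")]),
    EntityDescriptor("file_system", [
        ("type", "TEXT"), ("host", "TEXT"), ("protocol", "TEXT")],
        links=[("experiment_id", "experiment")], extended=False),
    EntityDescriptor("file", [
        ("path", "TEXT"), ("role", "TEXT"), ("size", "INTEGER")],
        links=[("file_system_id", "file_system"),
               ("task_id", "experiment_task"),
               ("system_id", "molecular_system"),
               ("format_id", "file_format")]),
]


def default_model_descriptor(dictionaries: DictionarySet) -> ModelDescriptor:
    """Descriptor covering the full logical model plus a dictionary set."""
    return ModelDescriptor(entities=list(_MODEL_ENTITIES),
                           dictionaries=dict(dictionaries))


def _dictionary_columns(dictionary: Dictionary):
    columns: list[str] = ["  id TEXT PRIMARY KEY"]
    constraints: list[str] = []
    for spec in dictionary.schema:
        if spec.name == "ID":
            continue
        column = spec.name.lower()
        if spec.kind == "link":
            columns.append(f"  {column} TEXT")
            constraints.append(
                f"  FOREIGN KEY ({column}) REFERENCES {spec.target} (id)")
        elif spec.kind == "bool":
            columns.append(f"  {column} INTEGER")
        elif spec.name == "TERM":
            columns.append("  term TEXT NOT NULL")
        else:
            columns.append(f"  {column} TEXT")
    return columns, constraints


def _dictionary_order(dictionaries: DictionarySet) -> list[str]:
    sorter = graphlib.TopologicalSorter()
    for name, dictionary in sorted(dictionaries.items()):
        targets = [s.target for s in dictionary.schema
                   if s.kind == "link" and s.target in dictionaries]
        sorter.add(name, *targets)
        for spec in dictionary.schema:
            if spec.kind == "link" and spec.target not in dictionaries:
                raise SchemaError(
                    f"dictionary {name!r} links to {spec.target!r}, which is "
                    "not part of the descriptor"
                )
    return list(sorter.static_order())


def generate_ddl(descriptor: ModelDescriptor, dialect: str = "generic") -> str:
    """Emit the full DDL script for a model descriptor.

    Dangling entity links (to a table neither an entity nor a dictionary
    declares) are generation errors.
    """
    if dialect not in ("generic", "sqlite"):
        raise SchemaError(f"unknown DDL dialect {dialect!r}")
    dict_order = _dictionary_order(descriptor.dictionaries)
    entity_names = {e.name for e in descriptor.entities}
    known_tables = entity_names | set(dict_order)
    for entity in descriptor.entities:
        for column, target in entity.links:
            if target not in known_tables:
                raise SchemaError(
                    f"entity {entity.name!r} links {column!r} to unknown "
                    f"table {target!r}"
                )

    statements: list[str] = []
    drop_order = (
        [f"{e.name}_extended_attribute" for e in descriptor.entities
         if e.extended]
        + [e.name for e in reversed(descriptor.entities)]
        + list(reversed(dict_order))
    )
    for table in drop_order:
        statements.append(f"DROP TABLE IF EXISTS {table};")

    for name in dict_order:
        columns, constraints = _dictionary_columns(
            descriptor.dictionaries[name])
        body = ",\n".join(columns + constraints)
        statements.append(f"CREATE TABLE {name} (\n{body}\n);")

    for entity in descriptor.entities:
        columns = ["  id TEXT PRIMARY KEY"]
        constraints = []
        for column, sql_type in entity.fields:
            quoted = f'"{column}"' if column in ("number", "text", "count",
                                                 "size") else column
            columns.append(f"  {quoted} {sql_type}")
        for column, target in entity.links:
            columns.append(f"  {column} TEXT")
            constraints.append(
                f"  FOREIGN KEY ({column}) REFERENCES {target} (id)")
        body = ",\n".join(columns + constraints)
        statements.append(f"CREATE TABLE {entity.name} (\n{body}\n);")
        if entity.extended:
            statements.append(
                f"CREATE TABLE {entity.name}_extended_attribute (\n"
                f"  id TEXT PRIMARY KEY,\n"
                f"  {entity.name}_id TEXT NOT NULL,\n"
                f"  attribute TEXT NOT NULL,\n"
                f"  value TEXT,\n"
                f"  unit TEXT,\n"
                f"  concept_id TEXT,\n"
                f"  FOREIGN KEY ({entity.name}_id) REFERENCES "
                f"{entity.name} (id)\n);"
            )
    return "\n\n".join(statements) + "\n"


def load_dictionaries_into(connection, dictionaries: DictionarySet) -> int:
    """Insert every entry of every dictionary; returns the row count.

    The connection must already hold the generated schema; foreign keys
    are enforced, so a dangling link surfaces as an integrity error.
    """
    connection.execute("PRAGMA foreign_keys = ON;")
    total = 0
    for name in _dictionary_order(dictionaries):
        dictionary = dictionaries[name]
        for entry in dictionary:
            columns = ["id", "term", "description"]
            values = [entry.id, entry.term, entry.description]
            for spec in dictionary.schema:
                if spec.name in ("ID", "TERM", "DESCRIPTION"):
                    continue
                column = spec.name.lower()
                if spec.name == "CITATION":
                    columns.append(column)
                    values.append(entry.citation)
                elif spec.kind == "link":
                    columns.append(column)
                    ref = entry.links.get(spec.name)
                    values.append(ref.target_id if ref else None)
                elif spec.kind == "bool":
                    columns.append(column)
                    raw = entry.extras.get(spec.name)
                    values.append(None if raw is None else int(bool(raw)))
                else:
                    columns.append(column)
                    values.append(entry.extras.get(spec.name))
            placeholders = ", ".join("?" for _ in values)
            connection.execute(
                f"INSERT INTO {name} ({', '.join(columns)}) "
                f"VALUES ({placeholders})", values)
            total += 1
    connection.commit()
    return total
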