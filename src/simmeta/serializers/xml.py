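"""XML experiment documents.

``to_xml`` mirrors the experiment tree — experiment, process groups,
processes, tasks, parameter sets, molecular systems, files — into an XML
document; ``from_xml`` validates a document against the published schema
(``data/experiment.xsd``) and rebuilds equal model objects.  Dependencies
serialize as id references, never nesting, so the document stays a tree;
molecular systems shared by several process groups are written once and
referenced by id.  Extended attributes travel as dedicated
``extendedAttribute`` elements carrying the attribute-value-unit triplet
plus an optional concept identifier.
"""

from __future__ import annotations

from importlib import resources

from lxml import etree

from ..errors import SerializationError
from ..model import (
    AtomOccurrence,
    Author,
    Barostat,
    Citation,
    ComputingEnvironment,
    Constraint,
    Experiment,
    ExtendedAttribute,
    FileReference,
    FileSystemRef,
    ForceField,
    Grant,
    MDParameterSet,
    MethodSpec,
    MolecularSystem,
    Molecule,
    Process,
    ProcessGroup,
    QMMMParameterSet,
    QMParameterSet,
    Quantity,
    ResidueOccurrence,
    Restraint,
    SimulatedConditions,
    Software,
    TaskExecution,
    TASK_TYPES,
    Thermostat,
    validate_experiment,
)

_schema_cache: etree.XMLSchema | None = None


def _schema() -> etree.XMLSchema:
    global _schema_cache
    if _schema_cache is None:
        data = (resources.files("simmeta")
                .joinpath("data", "experiment.xsd").read_bytes())
        _schema_cache = etree.XMLSchema(etree.fromstring(data))
    return _schema_cache


def _set(element, name, value):
    if value is None:
        return
    if isinstance(value, bool):
        value = "true" if value else "false"
    element.set(name, str(value))


def _get(element, name, convert=None):
    raw = element.get(name)
    if raw is None:
        return None
    if convert is bool:
        return raw == "true"
    return convert(raw) if convert else raw


def _quantity_element(parent, tag, quantity: Quantity | None):
    if quantity is None:
        return
    el = etree.SubElement(parent, tag)
    _set(el, "value", repr(quantity.value))
    _set(el, "unit", quantity.unit)


def _quantity_from(element, tag) -> Quantity | None:
    el = element.find(tag)
    if el is None:
        return None
    return Quantity(value=float(el.get("value")), unit=el.get("unit"))


def _extended_elements(parent, extended):
    for x in extended:
        el = etree.SubElement(parent, "extendedAttribute")
        _set(el, "attribute", x.attribute)
        _set(el, "value", x.value)
        _set(el, "unit", x.unit)
        _set(el, "conceptId", x.concept_id)


def _extended_from(element):
    return [
        ExtendedAttribute(
            attribute=el.get("attribute"),
            value=el.get("value"),
            unit=el.get("unit"),
            concept_id=el.get("conceptId"),
        )
        for el in element.findall("extendedAttribute")
    ]


def _file_element(parent, ref: FileReference):
    el = etree.SubElement(parent, "file")
    _set(el, "uid", ref.uid)
    _set(el, "path", ref.path)
    _set(el, "format", ref.format)
    _set(el, "role", ref.role)
    _set(el, "size", ref.size)
    _extended_elements(el, ref.extended)


def _file_from(el) -> FileReference:
    return FileReference(
        uid=el.get("uid"),
        path=el.get("path"),
        format=el.get("format"),
        role=el.get("role"),
        size=_get(el, "size", int),
        extended=_extended_from(el),
    )


def _depends_elements(parent, depends_on):
    for dep in depends_on:
        etree.SubElement(parent, "dependsOn").text = dep


def _depends_from(element):
    return [el.text for el in element.findall("dependsOn")]


# ---------------------------------------------------------------------------
# writer


def to_xml(experiment: Experiment) -> etree._ElementTree:
    """Serialize a valid experiment; refuses invalid ones with the report."""
    report = validate_experiment(experiment)
    if not report.valid:
        raise SerializationError(
            "refusing to serialize an invalid experiment:\n"
            + "\n".join(f"  {v.path}: {v.message}" for v in report.violations)
        )
    root = etree.Element("experiment")
    _set(root, "id", experiment.id)
    _set(root, "name", experiment.name)
    _set(root, "role", experiment.role)

    if experiment.author is not None:
        el = etree.SubElement(root, "author")
        _set(el, "name", experiment.author.name)
        _set(el, "institution", experiment.author.institution)
        _set(el, "contact", experiment.author.contact)
    for citation in experiment.citations:
        etree.SubElement(root, "citation").text = citation.text
    for grant in experiment.grants:
        el = etree.SubElement(root, "grant")
        _set(el, "agency", grant.agency)
        _set(el, "number", grant.number)

    for system in experiment.all_systems():
        _system_element(root, system)
    for group in experiment.process_groups:
        _group_element(root, group)
    for collection in experiment.file_collections:
        el = etree.SubElement(root, "fileCollection")
        _set(el, "type", collection.type)
        _set(el, "host", collection.host)
        _set(el, "protocol", collection.protocol)
        for ref in collection.files:
            _file_element(el, ref)
    _extended_elements(root, experiment.extended)
    return etree.ElementTree(root)


def _system_element(parent, system: MolecularSystem):
    el = etree.SubElement(parent, "system")
    _set(el, "id", system.id)
    _set(el, "name", system.name)
    for molecule in system.molecules:
        mel = etree.SubElement(el, "molecule")
        _set(mel, "name", molecule.name)
        _set(mel, "count", molecule.count)
        _set(mel, "type", molecule.molecule_type)
        for occ in molecule.residue_occurrences:
            oel = etree.SubElement(mel, "residueOccurrence")
            _set(oel, "name", occ.name)
            _set(oel, "count", occ.count)
            _set(oel, "symbol", occ.specific_symbol)
        for occ in molecule.atom_occurrences:
            oel = etree.SubElement(mel, "atomOccurrence")
            _set(oel, "element", occ.element)
            _set(oel, "count", occ.count)
            _set(oel, "symbol", occ.specific_symbol)
        if molecule.specific_chain:
            etree.SubElement(mel, "chain").text = ",".join(
                molecule.specific_chain)
        _extended_elements(mel, molecule.extended)
    for ref in system.topology_files:
        _file_element(el, ref)
    _extended_elements(el, system.extended)


def _group_element(parent, group: ProcessGroup):
    el = etree.SubElement(parent, "processGroup")
    _set(el, "id", group.id)
    if group.system is not None:
        _set(el, "systemRef", group.system.id)
    for process in group.processes:
        pel = etree.SubElement(el, "process")
        _set(pel, "id", process.id)
        for task in process.tasks:
            _task_element(pel, task)
        _depends_elements(pel, process.depends_on)
    _depends_elements(el, group.depends_on)


def _task_element(parent, task):
    el = etree.SubElement(parent, "task")
    _set(el, "kind", task.task_kind)
    _set(el, "id", task.id)
    _set(el, "methodName", task.method_name)
    _set(el, "description", task.description)
    _set(el, "boundaryConditions", task.boundary_conditions)
    _set(el, "solventType", task.solvent_type)
    for calculation in task.calculations:
        etree.SubElement(el, "calculation").text = calculation
    if task.conditions is not None:
        cel = etree.SubElement(el, "conditions")
        _quantity_element(cel, "referencePressure",
                          task.conditions.reference_pressure)
        _quantity_element(cel, "referenceTemperature",
                          task.conditions.reference_temperature)
    if task.environment is not None:
        env = task.environment
        eel = etree.SubElement(el, "environment")
        _set(eel, "os", env.os)
        _set(eel, "cpuArchitecture", env.cpu_architecture)
        _set(eel, "gpuArchitecture", env.gpu_architecture)
        _set(eel, "machineArchitecture", env.machine_architecture)
        _set(eel, "machineName", env.machine_name)
    if task.execution is not None:
        exe = task.execution
        xel = etree.SubElement(el, "execution")
        _set(xel, "start", exe.start)
        _set(xel, "end", exe.end)
        _set(xel, "elapsedSeconds",
             repr(exe.elapsed_seconds) if exe.elapsed_seconds is not None
             else None)
        _set(xel, "terminationStatus", exe.termination_status)
    if task.software is not None:
        sel = etree.SubElement(el, "software")
        _set(sel, "name", task.software.name)
        _set(sel, "version", task.software.version)
        _set(sel, "executable", task.software.executable)
    md = getattr(task, "md_parameters", None)
    if md is not None:
        _md_parameters_element(el, md)
    qm = getattr(task, "qm_parameters", None)
    if qm is not None:
        _qm_parameters_element(el, qm)
    qmmm = getattr(task, "qmmm_parameters", None)
    if qmmm is not None:
        qel = etree.SubElement(el, "qmmmParameterSet")
        _set(qel, "boundaryTreatment", qmmm.boundary_treatment)
        _extended_elements(qel, qmmm.extended)
    for ref in task.files:
        _file_element(el, ref)
    _depends_elements(el, task.depends_on)
    _extended_elements(el, task.extended)


def _md_parameters_element(parent, params: MDParameterSet):
    el = etree.SubElement(parent, "mdParameterSet")
    _set(el, "ensemble", params.ensemble)
    _set(el, "electrostaticsModel", params.electrostatics_model)
    _set(el, "nSteps", params.n_steps)
    for ff in params.force_fields:
        etree.SubElement(el, "forceField").set("name", ff.specific_name)
    for tag, stat in (("barostat", params.barostat),
                      ("thermostat", params.thermostat)):
        if stat is not None:
            sel = etree.SubElement(el, tag)
            _set(sel, "name", stat.implementation_name)
            _set(sel, "chainLength", stat.chain_length)
            _quantity_element(sel, "timeConstant", stat.time_constant)
    for constraint in params.constraints:
        cel = etree.SubElement(el, "constraint")
        _set(cel, "algorithm", constraint.algorithm)
        _set(cel, "target", constraint.target)
    for restraint in params.restraints:
        rel = etree.SubElement(el, "restraint")
        _set(rel, "property", restraint.restrained_property)
        _set(rel, "target", restraint.target)
    _quantity_element(el, "stepLength", params.step_length)
    _quantity_element(el, "collisionFrequency", params.collision_frequency)
    _extended_elements(el, params.extended)


def _qm_parameters_element(parent, params: QMParameterSet):
    el = etree.SubElement(parent, "qmParameterSet")
    if params.method is not None:
        _set(el, "methodName", params.method.specific_name)
    _set(el, "basisSet", params.basis_set_name)
    _set(el, "frozenCore", params.frozen_core)
    _set(el, "pseudopotentials", params.pseudopotentials)
    _set(el, "convergenceFlag", params.convergence_flag)
    _set(el, "convergenceCriteria", params.convergence_criteria)
    _quantity_element(el, "planeWaveCutoff", params.plane_wave_cutoff)
    _extended_elements(el, params.extended)


def to_xml_string(experiment: Experiment) -> str:
    return etree.tostring(to_xml(experiment).getroot(), pretty_print=True,
                          encoding="unicode")


# ---------------------------------------------------------------------------
# reader


def validate_document(document) -> None:
    """Validate against the published schema; raise with element path."""
    if isinstance(document, (str, bytes)):
        document = etree.fromstring(
            document.encode() if isinstance(document, str) else document)
    elif hasattr(document, "getroot"):
        document = document.getroot()
    schema = _schema()
    if not schema.validate(document):
        entry = schema.error_log[0]
        raise SerializationError(
            f"document violates the experiment schema at {entry.path}: "
            f"{entry.message}"
        )


def from_xml(document) -> Experiment:
    """Rebuild an experiment from a schema-valid document."""
    if isinstance(document, (str, bytes)):
        root = etree.fromstring(
            document.encode() if isinstance(document, str) else document)
    elif hasattr(document, "getroot"):
        root = document.getroot()
    else:
        root = document
    validate_document(root)

    systems: dict[str, MolecularSystem] = {}
    for el in root.findall("system"):
        system = _system_from(el)
        systems[system.id] = system

    experiment = Experiment(
        id=root.get("id"),
        name=root.get("name"),
        role=root.get("role"),
        extended=_extended_from(root),
    )
    ael = root.find("author")
    if ael is not None:
        experiment.author = Author(name=ael.get("name"),
                                   institution=ael.get("institution"),
                                   contact=ael.get("contact"))
    experiment.citations = [Citation(el.text)
                            for el in root.findall("citation")]
    experiment.grants = [Grant(agency=el.get("agency"),
                               number=el.get("number"))
                         for el in root.findall("grant")]
    for gel in root.findall("processGroup"):
        group = ProcessGroup(id=gel.get("id"),
                             depends_on=_depends_from(gel))
        ref = gel.get("systemRef")
        if ref is not None:
            if ref not in systems:
                raise SerializationError(
                    f"processGroup {group.id!r} references unknown system "
                    f"{ref!r}")
            group.system = systems[ref]
        for pel in gel.findall("process"):
            process = Process(id=pel.get("id"),
                              depends_on=_depends_from(pel))
            for tel in pel.findall("task"):
                process.tasks.append(_task_from(tel))
            group.processes.append(process)
        experiment.process_groups.append(group)
    for cel in root.findall("fileCollection"):
        experiment.file_collections.append(FileSystemRef(
            type=cel.get("type"),
            host=cel.get("host"),
            protocol=cel.get("protocol"),
            files=[_file_from(el) for el in cel.findall("file")],
        ))
    return experiment


def _system_from(el) -> MolecularSystem:
    molecules = []
    for mel in el.findall("molecule"):
        chain_el = mel.find("chain")
        molecules.append(Molecule(
            name=mel.get("name"),
            count=_get(mel, "count", int),
            molecule_type=mel.get("type"),
            residue_occurrences=[
                ResidueOccurrence(name=oel.get("name"),
                                  count=_get(oel, "count", int),
                                  specific_symbol=oel.get("symbol"))
                for oel in mel.findall("residueOccurrence")],
            atom_occurrences=[
                AtomOccurrence(element=oel.get("element"),
                               count=_get(oel, "count", int),
                               specific_symbol=oel.get("symbol"))
                for oel in mel.findall("atomOccurrence")],
            specific_chain=(chain_el.text.split(",")
                            if chain_el is not None and chain_el.text else []),
            extended=_extended_from(mel),
        ))
    return MolecularSystem(
        id=el.get("id"),
        name=el.get("name"),
        molecules=molecules,
        topology_files=[_file_from(f) for f in el.findall("file")],
        extended=_extended_from(el),
    )


def _task_from(el):
    kind = el.get("kind")
    if kind not in TASK_TYPES:
        raise SerializationError(f"unknown task kind {kind!r}")
    task = TASK_TYPES[kind](
        id=el.get("id"),
        method_name=el.get("methodName"),
        description=el.get("description"),
        boundary_conditions=el.get("boundaryConditions"),
        solvent_type=el.get("solventType"),
        calculations=[c.text for c in el.findall("calculation")],
        files=[_file_from(f) for f in el.findall("file")],
        depends_on=_depends_from(el),
        extended=_extended_from(el),
    )
    cel = el.find("conditions")
    if cel is not None:
        task.conditions = SimulatedConditions(
            reference_pressure=_quantity_from(cel, "referencePressure"),
            reference_temperature=_quantity_from(cel, "referenceTemperature"),
        )
    eel = el.find("environment")
    if eel is not None:
        task.environment = ComputingEnvironment(
            os=eel.get("os"),
            cpu_architecture=eel.get("cpuArchitecture"),
            gpu_architecture=eel.get("gpuArchitecture"),
            machine_architecture=eel.get("machineArchitecture"),
            machine_name=eel.get("machineName"),
        )
    xel = el.find("execution")
    if xel is not None:
        task.execution = TaskExecution(
            start=xel.get("start"),
            end=xel.get("end"),
            elapsed_seconds=_get(xel, "elapsedSeconds", float),
            termination_status=xel.get("terminationStatus"),
        )
    sel = el.find("software")
    if sel is not None:
        task.software = Software(name=sel.get("name"),
                                 version=sel.get("version"),
                                 executable=sel.get("executable"))
    mel = el.find("mdParameterSet")
    if mel is not None:
        task.md_parameters = _md_parameters_from(mel)
    qel = el.find("qmParameterSet")
    if qel is not None:
        task.qm_parameters = _qm_parameters_from(qel)
    qqel = el.find("qmmmParameterSet")
    if qqel is not None:
        task.qmmm_parameters = QMMMParameterSet(
            boundary_treatment=qqel.get("boundaryTreatment"),
            extended=_extended_from(qqel),
        )
    return task


def _md_parameters_from(el) -> MDParameterSet:
    params = MDParameterSet(
        ensemble=el.get("ensemble"),
        electrostatics_model=el.get("electrostaticsModel"),
        n_steps=_get(el, "nSteps", int),
        force_fields=[ForceField(f.get("name"))
                      for f in el.findall("forceField")],
        constraints=[Constraint(c.get("algorithm"), c.get("target"))
                     for c in el.findall("constraint")],
        restraints=[Restraint(r.get("property"), r.get("target"))
                    for r in el.findall("restraint")],
        step_length=_quantity_from(el, "stepLength"),
        collision_frequency=_quantity_from(el, "collisionFrequency"),
        extended=_extended_from(el),
    )
    bel = el.find("barostat")
    if bel is not None:
        params.barostat = Barostat(
            implementation_name=bel.get("name"),
            time_constant=_quantity_from(bel, "timeConstant"),
            chain_length=_get(bel, "chainLength", int),
        )
    tel = el.find("thermostat")
    if tel is not None:
        params.thermostat = Thermostat(
            implementation_name=tel.get("name"),
            time_constant=_quantity_from(tel, "timeConstant"),
            chain_length=_get(tel, "chainLength", int),
        )
    return params


def _qm_parameters_from(el) -> QMParameterSet:
    method = el.get("methodName")
    return QMParameterSet(
        method=MethodSpec(method) if method is not None else None,
        basis_set_name=el.get("basisSet"),
        frozen_core=_get(el, "frozenCore", bool),
        pseudopotentials=_get(el, "pseudopotentials", bool),
        convergence_flag=_get(el, "convergenceFlag", bool),
        convergence_criteria=el.get("convergenceCriteria"),
        plane_wave_cutoff=_quantity_from(el, "planeWaveCutoff"),
        extended=_extended_from(el),
    )
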