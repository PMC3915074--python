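"""Logical model of a virtual experiment.

A *virtual experiment* is the full set of dependent computational tasks
and files constituting one simulation study.  It decomposes into three
levels: *process groups* (all work targeting one molecular system, one
group per simulated copy), *processes* (a series of similar tasks, e.g.
all minimizations), and *tasks* (one computational run defined by an
input file).  Tasks reference reusable *parameter sets* — MD, QM, and
QM/MM bundles that can be combined to describe hybrid methods — plus the
software, computing environment and execution record of the run.

The molecular system is stored compactly as molecules with residue and
atom *occurrence counts* rather than individual instances: water is one
entry for H with count 2 and one for O with count 1, plus the count of
water molecules in the system.

Every entity can carry *extended attributes* — attribute-value-unit
triplets with an optional concept identifier — so labs can record
properties the model does not name (e.g. "PME interpolation order").
Extended attributes are multi-valued: attaching the same attribute twice
keeps both triplets.

Units are carried as opaque strings and never converted.  Derived
properties (method class/family, force-field type) are not stored here;
they are computed through the dictionaries when experiments are
flattened into an index.
"""

from __future__ import annotations

import graphlib
import hashlib
from dataclasses import dataclass, field, fields as dc_fields
from datetime import datetime

from .errors import CycleError, UsageError

PROCESS_KINDS = ("minimization", "md", "qm", "qmmm")


def deterministic_id(prefix: str, *parts) -> str:
    """Stable identifier derived from content and position.

    Parsers rarely supply entity ids; hashing content keeps regenerated
    fixtures reproducible.
    """
    digest = hashlib.sha1("\x1f".join(str(p) for p in parts).encode()).hexdigest()
    return f"{prefix}-{digest[:10]}"


@dataclass(frozen=True)
class Quantity:
    """A numeric value with an opaque unit string (never converted)."""

    value: float
    unit: str | None = None


@dataclass
class ExtendedAttribute:
    attribute: str
    value: str
    unit: str | None = None
    concept_id: str | None = None


@dataclass
class Author:
    name: str
    institution: str | None = None
    contact: str | None = None


@dataclass
class Citation:
    text: str


@dataclass
class Grant:
    agency: str
    number: str | None = None


@dataclass
class Software:
    name: str | None = None
    version: str | None = None
    executable: str | None = None


@dataclass
class ComputingEnvironment:
    os: str | None = None
    cpu_architecture: str | None = None
    gpu_architecture: str | None = None
    machine_architecture: str | None = None
    machine_name: str | None = None


@dataclass
class TaskExecution:
    start: str | None = None  # ISO-8601 timestamps
    end: str | None = None
    elapsed_seconds: float | None = None
    termination_status: str | None = None


@dataclass
class SimulatedConditions:
    reference_pressure: Quantity | None = None
    reference_temperature: Quantity | None = None


@dataclass
class ForceField:
    """A force field instance referenced by a run; the specific name is
    retained verbatim and optionally resolves against the force_field
    dictionary at flattening time."""

    specific_name: str


@dataclass
class Barostat:
    implementation_name: str
    time_constant: Quantity | None = None
    chain_length: int | None = None


@dataclass
class Thermostat:
    implementation_name: str
    time_constant: Quantity | None = None
    chain_length: int | None = None


@dataclass
class Constraint:
    algorithm: str  # e.g. SHAKE, LINCS
    target: str  # atom mask or textual description


@dataclass
class Restraint:
    restrained_property: str  # e.g. bond, angle
    target: str


@dataclass
class MDParameterSet:
    force_fields: list[ForceField] = field(default_factory=list)
    barostat: Barostat | None = None
    thermostat: Thermostat | None = None
    ensemble: str | None = None
    constraints: list[Constraint] = field(default_factory=list)
    restraints: list[Restraint] = field(default_factory=list)
    electrostatics_model: str | None = None
    collision_frequency: Quantity | None = None  # stochastic dynamics only
    n_steps: int | None = None
    step_length: Quantity | None = None
    extended: list[ExtendedAttribute] = field(default_factory=list)


@dataclass
class MethodSpec:
    """A method name as written in an input file; classification into
    class/family happens through dictionaries, not here."""

    specific_name: str


@dataclass
class QMParameterSet:
    method: MethodSpec | None = None
    basis_set_name: str | None = None
    frozen_core: bool | None = None
    pseudopotentials: bool | None = None
    plane_wave_cutoff: Quantity | None = None
    convergence_flag: bool | None = None
    convergence_criteria: str | None = None
    extended: list[ExtendedAttribute] = field(default_factory=list)


@dataclass
class QMMMParameterSet:
    boundary_treatment: str | None = None
    extended: list[ExtendedAttribute] = field(default_factory=list)


@dataclass
class FileReference:
    uid: str
    path: str
    format: str | None = None
    role: str = "input"  # input | output | topology
    size: int | None = None
    extended: list[ExtendedAttribute] = field(default_factory=list)


@dataclass
class FileSystemRef:
    type: str = "local"  # e.g. NFS, object store
    host: str | None = None
    protocol: str | None = None
    files: list[FileReference] = field(default_factory=list)


@dataclass
class ResidueOccurrence:
    name: str
    count: int
    specific_symbol: str | None = None


@dataclass
class AtomOccurrence:
    element: str
    count: int
    specific_symbol: str | None = None


@dataclass
class Molecule:
    name: str
    count: int = 1
    molecule_type: str | None = None  # e.g. RNA, protein, solvent, ion
    residue_occurrences: list[ResidueOccurrence] = field(default_factory=list)
    atom_occurrences: list[AtomOccurrence] = field(default_factory=list)
    specific_chain: list[str] = field(default_factory=list)
    extended: list[ExtendedAttribute] = field(default_factory=list)


@dataclass
class MolecularSystem:
    id: str
    name: str
    molecules: list[Molecule] = field(default_factory=list)
    topology_files: list[FileReference] = field(default_factory=list)
    extended: list[ExtendedAttribute] = field(default_factory=list)


@dataclass
class ExperimentTask:
    """One computational run.  Subclasses carry the method-specific
    parameter sets; common attributes of any method live here."""

    id: str
    method_name: str | None = None
    description: str | None = None
    boundary_conditions: str | None = None  # periodic | non-periodic
    solvent_type: str | None = None  # vacuum | implicit | explicit
    calculations: list[str] = field(default_factory=list)
    conditions: SimulatedConditions | None = None
    environment: ComputingEnvironment | None = None
    execution: TaskExecution | None = None
    software: Software | None = None
    files: list[FileReference] = field(default_factory=list)
    depends_on: list[str] = field(default_factory=list)
    extended: list[ExtendedAttribute] = field(default_factory=list)

    kind = "task"

    @property
    def parameter_sets(self) -> list:
        out = []
        for name in ("md_parameters", "qm_parameters", "qmmm_parameters"):
            ps = getattr(self, name, None)
            if ps is not None:
                out.append(ps)
        return out


@dataclass
class MinimizationTask(ExperimentTask):
    md_parameters: MDParameterSet | None = None
    task_kind = "minimization"


@dataclass
class MDTask(ExperimentTask):
    md_parameters: MDParameterSet | None = None
    task_kind = "md"


@dataclass
class QMTask(ExperimentTask):
    qm_parameters: QMParameterSet | None = None
    task_kind = "qm"


@dataclass
class QMMMTask(ExperimentTask):
    md_parameters: MDParameterSet | None = None
    qm_parameters: QMParameterSet | None = None
    qmmm_parameters: QMMMParameterSet | None = None
    task_kind = "qmmm"


TASK_TYPES = {
    "minimization": MinimizationTask,
    "md": MDTask,
    "qm": QMTask,
    "qmmm": QMMMTask,
}


@dataclass
class Process:
    id: str
    tasks: list[ExperimentTask] = field(default_factory=list)
    depends_on: list[str] = field(default_factory=list)

    kind = "process"


@dataclass
class ProcessGroup:
    id: str
    system: MolecularSystem | None = None
    processes: list[Process] = field(default_factory=list)
    depends_on: list[str] = field(default_factory=list)

    kind = "process_group"


@dataclass
class Experiment:
    id: str
    name: str
    role: str | None = None  # e.g. simulation, geometry optimization, docking
    author: Author | None = None
    citations: list[Citation] = field(default_factory=list)
    grants: list[Grant] = field(default_factory=list)
    process_groups: list[ProcessGroup] = field(default_factory=list)
    file_collections: list[FileSystemRef] = field(default_factory=list)
    extended: list[ExtendedAttribute] = field(default_factory=list)

    def all_tasks(self):
        for group in self.process_groups:
            for process in group.processes:
                yield from process.tasks

    def all_systems(self):
        seen = set()
        for group in self.process_groups:
            if group.system is not None and id(group.system) not in seen:
                seen.add(id(group.system))
                yield group.system


@dataclass
class ExperimentSet:
    name: str
    members: list[Experiment] = field(default_factory=list)

    def add(self, experiment: Experiment) -> None:
        if any(m is experiment or m.id == experiment.id for m in self.members):
            raise UsageError(
                f"experiment {experiment.id!r} is already a member of set "
                f"{self.name!r}"
            )
        self.members.append(experiment)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    path: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.valid

    def add(self, path: str, message: str) -> None:
        self.violations.append(Violation(path, message))


def _check_acyclic(entities, path: str, label: str, report: ValidationReport):
    by_id = {e.id: e for e in entities}
    sorter = graphlib.TopologicalSorter()
    for entity in entities:
        deps = [d for d in entity.depends_on if d in by_id]
        sorter.add(entity.id, *deps)
        for dep in entity.depends_on:
            if dep not in by_id:
                report.add(path, f"{label} {entity.id!r} depends on unknown "
                                 f"{label} {dep!r}")
    try:
        list(sorter.static_order())
    except graphlib.CycleError as exc:
        cycle = exc.args[1]
        report.add(path, f"dependency cycle among {label}s: "
                         + " -> ".join(cycle))


def validate_experiment(experiment: Experiment) -> ValidationReport:
    """Check every structural invariant; violations are data, not errors.

    An empty report means the experiment is valid.
    """
    report = ValidationReport()
    known_uids = {
        f.uid for coll in experiment.file_collections for f in coll.files
    }

    seen_processes: dict[int, str] = {}
    seen_tasks: dict[int, str] = {}
    _check_acyclic(experiment.process_groups, "experiment", "process group",
                   report)
    all_procs = [p for g in experiment.process_groups for p in g.processes]
    _check_acyclic(all_procs, "experiment", "process", report)
    all_tasks = list(experiment.all_tasks())
    _check_acyclic(all_tasks, "experiment", "task", report)

    for gi, group in enumerate(experiment.process_groups):
        gpath = f"experiment/process_group[{gi}]"
        if group.system is None:
            report.add(gpath, "process group has no molecular system")
        for pi, process in enumerate(group.processes):
            ppath = f"{gpath}/process[{pi}]"
            if id(process) in seen_processes:
                report.add(ppath, f"process {process.id!r} appears in more "
                                  f"than one process group "
                                  f"({seen_processes[id(process)]})")
            seen_processes[id(process)] = gpath
            kinds = {getattr(t, "task_kind", None) for t in process.tasks}
            if len(kinds) > 1:
                report.add(ppath, "process mixes task kinds: "
                           + ", ".join(sorted(str(k) for k in kinds)))
            for ti, task in enumerate(process.tasks):
                tpath = f"{ppath}/task[{ti}]"
                if id(task) in seen_tasks:
                    report.add(tpath, f"task {task.id!r} appears in more than "
                                      f"one process ({seen_tasks[id(task)]})")
                seen_tasks[id(task)] = ppath
                _validate_task(task, tpath, known_uids, report)
    return report


def _validate_task(task, path, known_uids, report):
    for fref in task.files:
        if fref.role == "topology":
            report.add(path, f"topology file {fref.path!r} must attach to "
                             "the molecular system, not a task")
        if known_uids and fref.uid not in known_uids:
            report.add(path, f"file {fref.uid!r} is not in any of the "
                             "experiment's file collections")
    if isinstance(task, MDTask):
        if task.md_parameters is None:
            report.add(path, "MD task has no MD parameter set")
        elif not task.md_parameters.force_fields:
            report.add(path, "MD parameter set declares no force field")
    if isinstance(task, QMTask):
        if task.qm_parameters is None or task.qm_parameters.method is None:
            report.add(path, "QM task has no method")
    if isinstance(task, QMMMTask):
        for attr in ("md_parameters", "qm_parameters", "qmmm_parameters"):
            if getattr(task, attr) is None:
                report.add(path, f"QM/MM task is missing {attr}")
        qmmm = task.qmmm_parameters
        if qmmm is not None and not qmmm.boundary_treatment:
            report.add(path, "QM/MM parameter set has an empty boundary "
                             "treatment")
    cond = task.conditions
    if cond is not None:
        for name in ("reference_pressure", "reference_temperature"):
            q = getattr(cond, name)
            if q is not None and q.value < 0:
                report.add(path, f"{name} is negative")
    exe = task.execution
    if exe is not None and exe.start and exe.end:
        try:
            start = datetime.fromisoformat(exe.start)
            end = datetime.fromisoformat(exe.end)
        except ValueError:
            report.add(path, "unparseable execution timestamps")
        else:
            if end < start:
                report.add(path, "execution end precedes start")
            elif exe.elapsed_seconds is not None:
                if abs((end - start).total_seconds() - exe.elapsed_seconds) > 1:
                    report.add(path, "elapsed time inconsistent with "
                                     "start/end timestamps")


# ---------------------------------------------------------------------------
# extended attributes and dependencies


def attach_extended_attribute(
    entity,
    attribute: str,
    value,
    unit: str | None = None,
    concept_id: str | None = None,
):
    """Append one attribute-value-unit triplet to an entity's extended list.

    Multi-valued by design: attaching the same attribute twice keeps both.
    Returns the entity for chaining.
    """
    if not attribute or not attribute.strip():
        raise UsageError("extended attribute name must be non-empty")
    entity.extended.append(
        ExtendedAttribute(attribute=attribute, value=str(value), unit=unit,
                          concept_id=concept_id)
    )
    return entity


def remove_extended_attribute(entity, attribute: str):
    """Remove all triplets with the given attribute name."""
    entity.extended = [x for x in entity.extended if x.attribute != attribute]
    return entity


def add_dependency(from_entity, to_entity, population):
    """Record that ``from_entity`` depends on ``to_entity``.

    Dependencies are legal between tasks, between processes, and between
    process groups — never across kinds.  The edge is rejected if it
    would create a cycle within ``population`` (the sibling entities at
    the same level).
    """
    if from_entity.kind != to_entity.kind:
        raise UsageError(
            f"cannot create a dependency from a {from_entity.kind} to a "
            f"{to_entity.kind}"
        )
    if from_entity is to_entity or from_entity.id == to_entity.id:
        raise CycleError(f"{from_entity.id!r} cannot depend on itself")
    proposed = list(from_entity.depends_on) + [to_entity.id]
    sorter = graphlib.TopologicalSorter()
    for entity in population:
        deps = proposed if entity is from_entity else entity.depends_on
        sorter.add(entity.id, *deps)
    try:
        sorter.prepare()
    except graphlib.CycleError as exc:
        raise CycleError(
            "dependency would create a cycle: " + " -> ".join(exc.args[1])
        ) from None
    from_entity.depends_on.append(to_entity.id)
    return population


def topological_order(entities) -> list:
    """Entities sorted so that every dependency precedes its dependents."""
    by_id = {e.id: e for e in entities}
    sorter = graphlib.TopologicalSorter()
    order_index = {e.id: i for i, e in enumerate(entities)}
    for entity in entities:
        sorter.add(entity.id, *[d for d in entity.depends_on if d in by_id])
    try:
        sorter.prepare()
    except graphlib.CycleError as exc:
        raise CycleError("cycle: " + " -> ".join(exc.args[1])) from None
    out = []
    while sorter.is_active():
        ready = sorted(sorter.get_ready(), key=order_index.__getitem__)
        out.extend(by_id[i] for i in ready)
        sorter.done(*ready)
    return out
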