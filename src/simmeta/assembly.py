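"""Assemble parsed task records into an experiment tree.

Grouping follows the three-level decomposition: one process group per
(molecular system, simulated copy) — a minimization-heating-production
series on one system is a single group with three processes, while two
simulated copies of the same system form two groups and separately
studied subsystems (ligand vs. receptor) get their own groups.  Within a
group, consecutive records of the same task kind collapse into one
process, and task dependencies follow file order.

Trajectory segment files are ordered by *natural* comparison — digit
runs compare numerically, so "2.traj" ranks before "10.traj" even
though a straight string comparison would invert them.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

from .errors import AssemblyError, UsageError
from .model import (
    Experiment,
    ExperimentTask,
    FileReference,
    FileSystemRef,
    MDTask,
    MinimizationTask,
    MolecularSystem,
    Process,
    ProcessGroup,
    QMTask,
    attach_extended_attribute,
    deterministic_id,
)
from .parsers import MDTaskRecord, QMTaskRecord

_TOKEN = re.compile(r"(\d+)")


def natural_key(name: str):
    """Sort key comparing digit runs numerically and text lexicographically.

    Leading zeros compare equal numerically ("02" = "2"); the shorter
    spelling wins the tie.  Digit runs order before text at the same
    position.
    """
    key = []
    for token in _TOKEN.split(name):
        if not token:
            continue
        if token.isdigit():
            key.append((0, int(token), len(token), ""))
        else:
            key.append((1, 0, 0, token))
    return tuple(key)


def order_task_files(names: Sequence[str]) -> list[str]:
    """Order file names naturally; stable for ties."""
    if not names:
        raise UsageError("file name list must be non-empty")
    return sorted(names, key=natural_key)


def ordering_is_lexicographic_fallback(names: Iterable[str]) -> bool:
    """True when no name carries a digit, so natural order degenerates to
    plain lexicographic order (flagged rather than guessed)."""
    return not any(any(c.isdigit() for c in name) for name in names)


def group_replicas(md_tasks: Sequence[ExperimentTask],
                   mode: str = "single_process") -> list[Process]:
    """Group the MD tasks of an enhanced-sampling run into processes.

    A 4-replica REMD run is legally either one process holding all four
    tasks (``single_process``, the default) or four single-task
    processes (``per_replica``).
    """
    if not md_tasks:
        raise UsageError("replica task list must be non-empty")
    if mode == "single_process":
        return [Process(id=deterministic_id("process", "replicas",
                                            *[t.id for t in md_tasks]),
                        tasks=list(md_tasks))]
    if mode == "per_replica":
        return [Process(id=deterministic_id("process", "replica", i, t.id),
                        tasks=[t])
                for i, t in enumerate(md_tasks)]
    raise UsageError(f"unknown replica grouping mode {mode!r}")


def _record_kind(record) -> str:
    """Process-grouping key: tasks are "similar" when they share a run
    context (minimization, heating, equilibration, production), so a
    minimization-heating-production series yields three processes."""
    if isinstance(record, QMTaskRecord):
        return "qm"
    return record.run_context or record.task_kind


def _task_from_record(record, index: int) -> ExperimentTask:
    source = record.source_file
    tid = deterministic_id("task", index,
                           source.uid if source else _record_kind(record))
    common = dict(
        id=tid,
        boundary_conditions=record.boundary_conditions,
        solvent_type=record.solvent_type,
        calculations=list(record.calculations),
        conditions=record.conditions,
        environment=record.environment,
        execution=record.execution,
        software=record.software,
        files=[source] if source else [],
    )
    if isinstance(record, QMTaskRecord):
        method = record.parameters.method
        return QMTask(method_name=method.specific_name if method else None,
                      qm_parameters=record.parameters, **common)
    if record.task_kind == "minimization":
        return MinimizationTask(method_name="Minimization",
                                description=record.run_context,
                                md_parameters=record.parameters, **common)
    return MDTask(method_name="Molecular dynamics",
                  description=record.run_context,
                  md_parameters=record.parameters, **common)


def assemble_experiment(
    systems: Sequence[MolecularSystem],
    records: Sequence,
    files: Sequence[FileReference] = (),
    name: str = "experiment",
    role: str | None = "simulation",
) -> Experiment:
    """Build a valid experiment from parsed systems, task records and files.

    Every record must resolve to exactly one system by name (a record
    without a system name resolves only when a single system is present).
    """
    if not systems:
        raise AssemblyError("at least one molecular system is required")
    by_name = {s.name: s for s in systems}

    # resolve (system, copy) group for each record, preserving input order
    groups: dict[tuple[str, int], list] = {}
    for record in records:
        if record.system_name is not None:
            system = by_name.get(record.system_name)
            if system is None:
                raise AssemblyError(
                    f"task record from "
                    f"{record.source_file.path if record.source_file else '?'} "
                    f"names unknown system {record.system_name!r}"
                )
        elif len(systems) == 1:
            system = systems[0]
        else:
            raise AssemblyError(
                "task record names no system and several systems are present"
            )
        copy = getattr(record, "copy_index", None) or 0
        groups.setdefault((system.name, copy), []).append(record)

    collection = FileSystemRef(type="local")
    seen_uids = set()

    def collect(ref: FileReference):
        if ref.uid not in seen_uids:
            seen_uids.add(ref.uid)
            collection.files.append(ref)

    for ref in files:
        collect(ref)
    for system in systems:
        for ref in system.topology_files:
            collect(ref)

    traj_files = [f for f in files if f.format == "TRAJ"]
    traj_order = (order_task_files([f.uid for f in traj_files])
                  if traj_files else [])
    traj_by_uid = {f.uid: f for f in traj_files}

    process_groups: list[ProcessGroup] = []
    for (system_name, copy), group_records in groups.items():
        system = by_name[system_name]
        group = ProcessGroup(
            id=deterministic_id("group", system_name, copy),
            system=system,
        )
        # consecutive same-kind tasks form one process; dependencies follow
        # task order across run boundaries (tasks inside one run — e.g.
        # replicas — may execute in parallel)
        tasks: list[ExperimentTask] = []
        runs: list[tuple[str, list[ExperimentTask]]] = []
        for record in group_records:
            task = _task_from_record(record, len(tasks))
            kind = _record_kind(record)
            if runs and runs[-1][0] == kind:
                runs[-1][1].append(task)
            else:
                if runs:
                    task.depends_on.append(runs[-1][1][-1].id)
                runs.append((kind, [task]))
            tasks.append(task)
        previous = None
        for kind, run_tasks in runs:
            process = Process(
                id=deterministic_id("process", group.id, kind, len(group.processes)),
                tasks=run_tasks,
            )
            if previous is not None:
                process.depends_on.append(previous.id)
            group.processes.append(process)
            previous = process
        # trajectory segments attach to the last MD task, in natural order
        md_tasks = [t for t in tasks if isinstance(t, MDTask)]
        if md_tasks and traj_order:
            md_tasks[-1].files.extend(traj_by_uid[uid] for uid in traj_order)
        for task in tasks:
            for ref in task.files:
                collect(ref)
        process_groups.append(group)

    experiment = Experiment(
        id=deterministic_id("experiment", name,
                            *[s.name for s in systems]),
        name=name,
        role=role,
        process_groups=process_groups,
        file_collections=[collection] if collection.files else [],
    )
    if traj_files and ordering_is_lexicographic_fallback(traj_by_uid):
        attach_extended_attribute(
            experiment, "trajectory ordering",
            "lexicographic fallback (no digits in segment names)")
    return experiment


def load_study_directory(directory):
    """Parse every recognized file in a study directory.

    Returns (systems, records, other_files): SIMTOP files become
    molecular systems, MDLOG/QMLOG files become task records (in natural
    file order), and everything else — inputs, trajectory segments —
    becomes plain file references.
    """
    from pathlib import Path

    from .parsers import detect_format, parse_md_output, parse_qm_output, \
        parse_topology

    directory = Path(directory)
    systems, records, other = [], [], []
    names = order_task_files([p.name for p in directory.iterdir()
                              if p.is_file()])
    for name in names:
        path = directory / name
        fmt = detect_format(path)
        if fmt == "SIMTOP":
            systems.append(parse_topology(path))
        elif fmt == "MDLOG":
            records.append(parse_md_output(path))
        elif fmt == "QMLOG":
            records.append(parse_qm_output(path))
        elif name != "manifest.json":
            role = "output" if fmt == "TRAJ" else "input"
            other.append(FileReference(uid=name, path=str(path), format=fmt,
                                       role=role,
                                       size=path.stat().st_size))
    return systems, records, other


def assemble_directory(directory, name: str | None = None,
                       replica_mode: str = "single_process") -> Experiment:
    """Parse and assemble a whole study directory into an experiment."""
    from pathlib import Path

    systems, records, other = load_study_directory(directory)
    experiment = assemble_experiment(
        systems, records, other,
        name=name or Path(directory).name)
    if replica_mode == "per_replica":
        for group in experiment.process_groups:
            regrouped = []
            previous = None
            for process in group.processes:
                parts = ([process] if len(process.tasks) <= 1
                         else group_replicas(process.tasks, "per_replica"))
                for part in parts:
                    part.depends_on = [previous.id] if previous else []
                    regrouped.append(part)
                    previous = part
            group.processes = regrouped
    elif replica_mode != "single_process":
        raise UsageError(f"unknown replica mode {replica_mode!r}")
    return experiment
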