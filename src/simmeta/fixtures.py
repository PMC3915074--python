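"""Deterministic generators for fixture experiment directories.

Each generator writes a study directory in the documented dialects —
one SIMTOP topology plus per-stage MDLOG/QMLOG outputs and their
inputs — and returns a manifest carrying the *exact* model objects the
tree must parse back to, so parsers, assembly, indexing and
serialization are all testable without any real simulation data.

All content flows from a single seeded generator and config-supplied
timestamps; regeneration with equal (seed, config) is byte-identical.
An MD study emulates the classic minimization-heating-production
series on a solvated RNA duplex (explicit TIP3P-like water, ~1000
water molecules, 2 fs production steps, 300 K / 1 bar reference
conditions); trajectory segments are numbered past ten so a naive
string sort of their names mis-orders them (e.g. "10.traj" before
"2.traj") and the natural-ordering path stays exercised.  Trajectory
payloads are placeholders: correct names, sizes and counts only.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import UsageError
from .model import (
    AtomOccurrence,
    Barostat,
    ComputingEnvironment,
    Constraint,
    FileReference,
    ForceField,
    MDParameterSet,
    MethodSpec,
    MolecularSystem,
    Molecule,
    QMParameterSet,
    Quantity,
    ResidueOccurrence,
    SimulatedConditions,
    Software,
    TaskExecution,
    Thermostat,
    deterministic_id,
)
from .parsers import MDTaskRecord, QMTaskRecord

STAGES = ("minimization", "heating", "production")

#: atoms contributed per nucleotide residue in the fixture topology
_RESIDUE_ATOMS = {"C": 9, "N": 4, "O": 6, "H": 11, "P": 1}


@dataclass(frozen=True)
class MDStudyConfig:
    stages: tuple[str, ...] = STAGES
    system_name: str = "RNA duplex in explicit water"
    solute_name: str = "RNA"
    solute_type: str = "RNA"
    chain_length: int = 12
    explicit_water: bool = True
    force_fields: tuple[str, ...] = ("AMBER FF99SB", "TIP3P")
    n_traj: int = 12
    copies: int = 1
    start_timestamp: str = "2013-05-01T10:00:00"


@dataclass(frozen=True)
class QMStudyConfig:
    system_name: str = "guanine"
    method: str = "MP2"
    basis_set: str = "6-31G*"
    executable: str = "EM64L-G09RevC.01"
    software: str = "Gaussian"
    version: str = "09"
    frozen_core: bool = True
    calculation: str = "Geometry optimization"
    start_timestamp: str = "2013-06-10T08:00:00"


@dataclass
class FixtureManifest:
    """Ground truth for one generated study directory."""

    seed: int
    config: object
    directory: Path
    system: MolecularSystem | None
    records: list = field(default_factory=list)
    input_files: list[FileReference] = field(default_factory=list)
    traj_files: list[FileReference] = field(default_factory=list)
    traj_order: list[str] = field(default_factory=list)
    n_process_groups: int = 1
    n_processes: int = 1
    replica_grouping: dict | None = None

    def write_json(self) -> Path:
        """Dump a plain-data summary next to the tree."""
        payload = {
            "seed": self.seed,
            "config": asdict(self.config),
            "system": self.system.name if self.system else None,
            "records": [r.source_file.uid for r in self.records],
            "traj_order": self.traj_order,
            "n_process_groups": self.n_process_groups,
            "n_processes": self.n_processes,
            "replica_grouping": self.replica_grouping,
        }
        path = self.directory / "manifest.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
        return path


def _write(path: Path, lines: list[str]) -> FileReference:
    content = "\n".join(lines) + "\n"
    path.write_text(content, encoding="utf-8")
    fmt = "unknown"
    first = lines[0] if lines else ""
    for magic, term in (("%SIMTOP", "SIMTOP"), ("%MDLOG", "MDLOG"),
                        ("%QMLOG", "QMLOG"), ("%TRAJ", "TRAJ")):
        if first.startswith(magic):
            fmt = term
            break
    role = "output" if fmt in ("MDLOG", "QMLOG", "TRAJ") else "input"
    return FileReference(uid=path.name, path=str(path), format=fmt, role=role,
                         size=len(content.encode("utf-8")))


def _timestamps(start: str, offset_s: int, elapsed_s: int):
    from datetime import datetime, timedelta

    base = datetime.fromisoformat(start) + timedelta(seconds=offset_s)
    end = base + timedelta(seconds=elapsed_s)
    return base.isoformat(), end.isoformat()


# ---------------------------------------------------------------------------
# MD study


def _build_system(rng: random.Random, config: MDStudyConfig,
                  directory: Path) -> tuple[MolecularSystem, FileReference]:
    chain = [rng.choice("AUGC") for _ in range(config.chain_length)]
    n_waters = rng.randrange(800, 1200)

    lines = ["%SIMTOP 1.0", "%SECTION SYSTEM",
             f"NAME = {config.system_name}",
             f"MOLECULE_TYPES = {2 if config.explicit_water else 1}",
             "%SECTION MOLECULE",
             f"NAME = {config.solute_name}",
             "COUNT = 1",
             f"TYPE = {config.solute_type}",
             f"N_RESIDUES = {len(chain)}",
             f"RESIDUES = {','.join(chain)}",
             "ATOMS = " + ",".join(
                 f"{el}:{n * len(chain)}"
                 for el, n in _RESIDUE_ATOMS.items())]
    if config.explicit_water:
        lines += ["%SECTION MOLECULE", "NAME = WAT",
                  f"COUNT = {n_waters}", "TYPE = solvent",
                  "N_RESIDUES = 1", "RESIDUES = WAT", "ATOMS = H:2,O:1"]
    ref = _write(directory / "topology.simtop", lines)
    ref.role = "topology"

    res_counts: dict[str, int] = {}
    for residue in chain:
        res_counts[residue] = res_counts.get(residue, 0) + 1
    molecules = [Molecule(
        name=config.solute_name, count=1, molecule_type=config.solute_type,
        residue_occurrences=[ResidueOccurrence(name=r, count=c)
                             for r, c in res_counts.items()],
        atom_occurrences=[AtomOccurrence(element=el, count=n * len(chain))
                          for el, n in _RESIDUE_ATOMS.items()],
        specific_chain=chain,
    )]
    if config.explicit_water:
        molecules.append(Molecule(
            name="WAT", count=n_waters, molecule_type="solvent",
            residue_occurrences=[ResidueOccurrence(name="WAT", count=1)],
            atom_occurrences=[AtomOccurrence(element="H", count=2),
                              AtomOccurrence(element="O", count=1)],
            specific_chain=["WAT"],
        ))
    system = MolecularSystem(
        id=deterministic_id("system", config.system_name,
                            *[m.name for m in molecules]),
        name=config.system_name,
        molecules=molecules,
        topology_files=[ref],
    )
    return system, ref


def _md_stage(rng: random.Random, config: MDStudyConfig, directory: Path,
              stage: str, index: int, copy: int | None):
    """Write one stage's input/output pair; return (refs, expected record)."""
    prefix = f"c{copy}_" if copy is not None else ""
    stem = f"{prefix}{index + 1:02d}_{stage}"
    solvent = "explicit" if config.explicit_water else "implicit"
    boundary = "periodic" if config.explicit_water else "non-periodic"
    thermostat = rng.choice(("Langevin", "Berendsen"))
    executable = rng.choice(("SANDER", "PMEMD"))
    machine = rng.choice(("kingspeak.chpc.utah.edu", "stampede.tacc.utexas.edu"))
    elapsed = rng.randrange(600, 7200)
    start, end = _timestamps(config.start_timestamp,
                             offset_s=(copy or 0) * 90000 + index * 10000,
                             elapsed_s=elapsed)

    in_ref = _write(directory / f"{stem}.in",
                    [f"# {stage} input parameters",
                     f"stage = {stage}"])

    lines = ["%MDLOG 1.0",
             f"SYSTEM = {config.system_name}"]
    if copy is not None:
        lines.append(f"COPY = {copy}")
    task_kind = "minimization" if stage == "minimization" else "md"
    lines += [f"TASK_KIND = {task_kind}",
              f"RUN_CONTEXT = {stage}",
              "SOFTWARE = AMBER", "VERSION = 12",
              f"EXECUTABLE = {executable}",
              "OS = Linux", "CPU_ARCH = x86_64",
              f"MACHINE_NAME = {machine}",
              f"BOUNDARY_CONDITIONS = {boundary}",
              f"SOLVENT_TYPE = {solvent}",
              "FORCE_FIELDS = " + ";".join(config.force_fields)]

    params = MDParameterSet(
        force_fields=[ForceField(n) for n in config.force_fields])
    conditions = None
    calculation = "Minimization" if task_kind == "minimization" else "Dynamics"
    lines.append(f"CALCULATION = {calculation}")

    if stage == "minimization":
        n_steps = rng.randrange(200, 1000)
        lines.append(f"N_STEPS = {n_steps}")
        params.n_steps = n_steps
    else:
        n_steps = (rng.randrange(10000, 50000) if stage == "heating"
                   else rng.randrange(100000, 500000))
        temperature = 300.0
        lines += [f"N_STEPS = {n_steps}", "STEP_LENGTH_PS = 0.002",
                  f"THERMOSTAT = {thermostat}",
                  f"REF_TEMPERATURE_K = {temperature}"]
        params.n_steps = n_steps
        params.step_length = Quantity(0.002, "ps")
        params.thermostat = Thermostat(implementation_name=thermostat)
        pressure = None
        if thermostat == "Langevin":
            lines.append("COLLISION_FREQUENCY_PS = 2.0")
            params.collision_frequency = Quantity(2.0, "1/ps")
        if stage == "production":
            lines += ["ENSEMBLE = NPT", "BAROSTAT = Berendsen",
                      "REF_PRESSURE_BAR = 1.0",
                      "ELECTROSTATICS = PME",
                      "CONSTRAINTS = SHAKE:bonds involving hydrogen"]
            params.ensemble = "NPT"
            params.barostat = Barostat(implementation_name="Berendsen")
            params.electrostatics_model = "PME"
            params.constraints = [Constraint("SHAKE",
                                             "bonds involving hydrogen")]
            pressure = Quantity(1.0, "bar")
        else:
            lines.append("ENSEMBLE = NVT")
            params.ensemble = "NVT"
        conditions = SimulatedConditions(
            reference_pressure=pressure,
            reference_temperature=Quantity(temperature, "K"))

    lines += [f"START = {start}", f"END = {end}",
              f"ELAPSED_SECONDS = {float(elapsed)}",
              "FOOTER: COMPLETE"]
    out_ref = _write(directory / f"{stem}.out", lines)

    record = MDTaskRecord(
        task_kind=task_kind,
        run_context=stage,
        parameters=params,
        conditions=conditions,
        software=Software(name="AMBER", version="12", executable=executable),
        environment=ComputingEnvironment(os="Linux",
                                         cpu_architecture="x86_64",
                                         machine_name=machine),
        execution=TaskExecution(start=start, end=end,
                                elapsed_seconds=float(elapsed),
                                termination_status="complete"),
        boundary_conditions=boundary,
        solvent_type=solvent,
        calculations=[calculation],
        system_name=config.system_name,
        copy_index=copy,
        source_file=out_ref,
    )
    return in_ref, out_ref, record


def generate_md_study(directory, seed: int,
                      config: MDStudyConfig | None = None) -> FixtureManifest:
    """Generate an MD study tree (topology, stage inputs/outputs,
    numbered trajectory segments) plus its ground-truth manifest."""
    config = config or MDStudyConfig()
    if not config.stages:
        raise UsageError("at least one stage is required")
    for stage in config.stages:
        if stage not in STAGES:
            raise UsageError(f"unknown stage {stage!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    system, _topology = _build_system(rng, config, directory)
    manifest = FixtureManifest(seed=seed, config=config, directory=directory,
                               system=system)

    copies = range(1, config.copies + 1) if config.copies > 1 else [None]
    for copy in copies:
        for index, stage in enumerate(config.stages):
            in_ref, _out_ref, record = _md_stage(rng, config, directory,
                                                 stage, index, copy)
            manifest.input_files.append(in_ref)
            manifest.records.append(record)

    if "production" in config.stages and config.n_traj:
        for segment in range(1, config.n_traj + 1):
            ref = _write(directory / f"{segment}.traj",
                         [f"%TRAJ segment {segment}",
                          f"frames = {rng.randrange(100, 500)}"])
            manifest.traj_files.append(ref)
        manifest.traj_order = [f"{i}.traj" for i in range(1, config.n_traj + 1)]

    manifest.n_process_groups = max(config.copies, 1)
    manifest.n_processes = len(config.stages) * manifest.n_process_groups
    manifest.write_json()
    return manifest


# ---------------------------------------------------------------------------
# REMD study


def generate_remd_study(directory, seed: int, n_replicas: int = 4,
                        config: MDStudyConfig | None = None) -> FixtureManifest:
    """Generate a temperature-REMD study: one MD output per replica.

    The manifest records both legal process groupings: the whole run as
    one process, or one process per replica.
    """
    if n_replicas < 1:
        raise UsageError("n_replicas must be >= 1")
    config = config or MDStudyConfig(system_name="RNA hairpin in explicit water",
                                     chain_length=8, n_traj=12)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    system, _topology = _build_system(rng, config, directory)
    manifest = FixtureManifest(seed=seed, config=config, directory=directory,
                               system=system)

    machine = rng.choice(("kingspeak.chpc.utah.edu", "keeneland.gatech.xsede.org"))
    for replica in range(1, n_replicas + 1):
        temperature = 300.0 + 10.0 * (replica - 1)
        elapsed = rng.randrange(3600, 7200)
        start, end = _timestamps(config.start_timestamp,
                                 offset_s=0, elapsed_s=elapsed)
        n_steps = rng.randrange(100000, 200000)
        lines = ["%MDLOG 1.0",
                 f"SYSTEM = {config.system_name}",
                 "TASK_KIND = md",
                 "RUN_CONTEXT = production",
                 "SOFTWARE = AMBER", "VERSION = 12", "EXECUTABLE = SANDER",
                 "OS = Linux", "CPU_ARCH = x86_64",
                 f"MACHINE_NAME = {machine}",
                 "BOUNDARY_CONDITIONS = periodic",
                 "SOLVENT_TYPE = explicit",
                 "FORCE_FIELDS = " + ";".join(config.force_fields),
                 "CALCULATION = Dynamics",
                 f"N_STEPS = {n_steps}", "STEP_LENGTH_PS = 0.002",
                 "THERMOSTAT = Langevin", "COLLISION_FREQUENCY_PS = 2.0",
                 "ENSEMBLE = generalized",
                 f"REF_TEMPERATURE_K = {temperature}",
                 f"START = {start}", f"END = {end}",
                 f"ELAPSED_SECONDS = {float(elapsed)}",
                 "FOOTER: COMPLETE"]
        out_ref = _write(directory / f"remd_r{replica}.out", lines)
        params = MDParameterSet(
            force_fields=[ForceField(n) for n in config.force_fields],
            thermostat=Thermostat(implementation_name="Langevin"),
            collision_frequency=Quantity(2.0, "1/ps"),
            ensemble="generalized",
            n_steps=n_steps,
            step_length=Quantity(0.002, "ps"),
        )
        manifest.records.append(MDTaskRecord(
            task_kind="md",
            run_context="production",
            parameters=params,
            conditions=SimulatedConditions(
                reference_temperature=Quantity(temperature, "K")),
            software=Software(name="AMBER", version="12",
                              executable="SANDER"),
            environment=ComputingEnvironment(os="Linux",
                                             cpu_architecture="x86_64",
                                             machine_name=machine),
            execution=TaskExecution(start=start, end=end,
                                    elapsed_seconds=float(elapsed),
                                    termination_status="complete"),
            boundary_conditions="periodic",
            solvent_type="explicit",
            calculations=["Dynamics"],
            system_name=config.system_name,
            source_file=out_ref,
        ))

    for segment in range(1, config.n_traj + 1):
        ref = _write(directory / f"{segment}.traj",
                     [f"%TRAJ segment {segment}",
                      f"frames = {rng.randrange(100, 500)}"])
        manifest.traj_files.append(ref)
    manifest.traj_order = [f"{i}.traj" for i in range(1, config.n_traj + 1)]

    manifest.n_process_groups = 1
    manifest.n_processes = 1  # default single_process grouping
    manifest.replica_grouping = {"single_process": 1, "per_replica": n_replicas}
    manifest.write_json()
    return manifest


# ---------------------------------------------------------------------------
# QM study


def generate_qm_study(directory, seed: int,
                      config: QMStudyConfig | None = None) -> FixtureManifest:
    """Generate a QM study: one input/output pair whose output embeds an
    ``<ARCH>-<PRODUCT>Rev<REVISION>`` executable string."""
    config = config or QMStudyConfig()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    elapsed = rng.randrange(120, 3600)
    start, end = _timestamps(config.start_timestamp, offset_s=0,
                             elapsed_s=elapsed)
    machine = rng.choice(("ember.chpc.utah.edu", "h2ologin.ncsa.illinois.edu"))

    # a minimal small-molecule topology (in QM the topology often lives in
    # the input file; the fixture keeps it separate for uniform parsing)
    topo_ref = _write(directory / "topology.simtop",
                      ["%SIMTOP 1.0", "%SECTION SYSTEM",
                       f"NAME = {config.system_name}",
                       "MOLECULE_TYPES = 1",
                       "%SECTION MOLECULE",
                       f"NAME = {config.system_name}",
                       "COUNT = 1", "TYPE = small molecule",
                       "N_RESIDUES = 1",
                       f"RESIDUES = {config.system_name.upper()[:3]}",
                       "ATOMS = C:5,N:5,O:1,H:5"])
    topo_ref.role = "topology"
    residue = config.system_name.upper()[:3]
    system = MolecularSystem(
        id=deterministic_id("system", config.system_name, config.system_name),
        name=config.system_name,
        molecules=[Molecule(
            name=config.system_name, count=1,
            molecule_type="small molecule",
            residue_occurrences=[ResidueOccurrence(name=residue, count=1)],
            atom_occurrences=[AtomOccurrence(element="C", count=5),
                              AtomOccurrence(element="N", count=5),
                              AtomOccurrence(element="O", count=1),
                              AtomOccurrence(element="H", count=5)],
            specific_chain=[residue],
        )],
        topology_files=[topo_ref],
    )

    in_ref = _write(directory / "qm.in",
                    ["# qm input", f"method = {config.method}",
                     f"basis = {config.basis_set}"])
    lines = ["%QMLOG 1.0",
             f"SYSTEM = {config.system_name}",
             f"SOFTWARE = {config.software}",
             f"VERSION = {config.version}",
             f"EXECUTABLE = {config.executable}",
             "OS = Linux", "CPU_ARCH = x86_64",
             f"MACHINE_NAME = {machine}",
             "BOUNDARY_CONDITIONS = non-periodic",
             "SOLVENT_TYPE = vacuum",
             f"CALCULATION = {config.calculation}",
             f"METHOD = {config.method}",
             f"BASIS_SET = {config.basis_set}",
             f"FROZEN_CORE = {'true' if config.frozen_core else 'false'}",
             "CONVERGED = true",
             f"START = {start}", f"END = {end}",
             f"ELAPSED_SECONDS = {float(elapsed)}",
             "FOOTER: COMPLETE"]
    out_ref = _write(directory / "qm.out", lines)

    manifest = FixtureManifest(
        seed=seed, config=config, directory=directory,
        system=system,
        input_files=[in_ref],
    )
    manifest.records.append(QMTaskRecord(
        parameters=QMParameterSet(
            method=MethodSpec(config.method),
            basis_set_name=config.basis_set,
            frozen_core=config.frozen_core,
            convergence_flag=True,
        ),
        software=Software(name=config.software, version=config.version,
                          executable=config.executable),
        environment=ComputingEnvironment(os="Linux",
                                         cpu_architecture="x86_64",
                                         machine_name=machine),
        execution=TaskExecution(start=start, end=end,
                                elapsed_seconds=float(elapsed),
                                termination_status="complete"),
        boundary_conditions="non-periodic",
        solvent_type="vacuum",
        calculations=[config.calculation],
        system_name=config.system_name,
        source_file=out_ref,
    ))
    manifest.n_process_groups = 1
    manifest.n_processes = 1
    manifest.write_json()
    return manifest
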