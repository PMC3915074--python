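"""Parsers for the plain-text fixture dialects and format detection.

Three line-oriented dialects stand in for real simulation engine formats;
they carry the same metadata a topology file, an MD output log and a QM
output log would, without the grammar complexity of engine-specific
files.  All three are documented in ``docs/fixture-dialects.md``.

* ``SIMTOP`` — topology: ``%SIMTOP`` magic, then ``%SECTION`` blocks
  (one SYSTEM block, one MOLECULE block per molecule type) of
  ``KEY = value`` lines.
* ``MDLOG`` — minimization/MD output: ``%MDLOG`` magic, ``KEY = value``
  lines, and a ``FOOTER: <status>`` line whose absence marks an
  incomplete run.
* ``QMLOG`` — QM output: same shape as MDLOG with QM-specific keys.

Parsers never invent values: a key absent from the file leaves the
corresponding field unset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .dictionaries import Dictionary, load_packaged_dictionaries
from .errors import ParseError, UsageError
from .model import (
    Barostat,
    ComputingEnvironment,
    Constraint,
    FileReference,
    ForceField,
    MDParameterSet,
    MethodSpec,
    Molecule,
    MolecularSystem,
    AtomOccurrence,
    QMParameterSet,
    Quantity,
    ResidueOccurrence,
    Restraint,
    SimulatedConditions,
    Software,
    TaskExecution,
    Thermostat,
    deterministic_id,
)

#: executables recognized as engine names even without an ARCH-PRODUCT-Rev
#: pattern (e.g. the two alternatives for running MD within AMBER).
KNOWN_ENGINE_EXECUTABLES = ("SANDER", "PMEMD", "CPPTRAJ", "NAMD2", "MDRUN")

_EXECUTABLE_PATTERN = re.compile(
    r"^(?P<arch>[A-Za-z0-9_]+)-(?P<product>[A-Za-z0-9]+?)Rev(?P<revision>.+)$"
)


@dataclass
class SoftwareBuildInfo:
    """Build details recovered from an executable name.

    ``EM64L-G09RevC.01`` gives product G09, revision C.01, and target
    architecture EM64L; the raw string is always retained.
    """

    raw: str
    product: str | None = None
    revision: str | None = None
    target_architecture: str | None = None


@dataclass
class MDTaskRecord:
    """Everything extracted from one MDLOG output file."""

    task_kind: str  # minimization | md
    run_context: str | None = None  # e.g. heating, equilibration, production
    parameters: MDParameterSet = field(default_factory=MDParameterSet)
    conditions: SimulatedConditions | None = None
    software: Software | None = None
    environment: ComputingEnvironment | None = None
    execution: TaskExecution | None = None
    boundary_conditions: str | None = None
    solvent_type: str | None = None
    calculations: list[str] = field(default_factory=list)
    system_name: str | None = None
    copy_index: int | None = None
    source_file: FileReference | None = None


@dataclass
class QMTaskRecord:
    """Everything extracted from one QMLOG output file."""

    parameters: QMParameterSet = field(default_factory=QMParameterSet)
    conditions: SimulatedConditions | None = None
    software: Software | None = None
    environment: ComputingEnvironment | None = None
    execution: TaskExecution | None = None
    boundary_conditions: str | None = None
    solvent_type: str | None = None
    calculations: list[str] = field(default_factory=list)
    system_name: str | None = None
    source_file: FileReference | None = None


# ---------------------------------------------------------------------------
# format detection


def detect_format(source) -> str:
    """Return a file_format dictionary term for a file, or "unknown".

    Detection looks at content only: the fixture dialects declare magic
    first lines, and PDB is recognized by its record keywords (so e.g. a
    file of ``ATOM`` records maps to File format = "PDB").
    """
    text = _read_text(source)
    stripped = text.lstrip()
    if not stripped:
        return "unknown"
    first = stripped.splitlines()[0]
    for magic, term in (("%SIMTOP", "SIMTOP"), ("%MDLOG", "MDLOG"),
                        ("%QMLOG", "QMLOG"), ("%TRAJ", "TRAJ")):
        if first.startswith(magic):
            return term
    for line in text.splitlines():
        if line.startswith(("ATOM  ", "HETATM", "HEADER")):
            return "PDB"
    return "unknown"


def _read_text(source) -> str:
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8")
    if isinstance(source, str) and "\n" not in source and Path(source).is_file():
        return Path(source).read_text(encoding="utf-8")
    if isinstance(source, bytes):
        return source.decode("utf-8", errors="replace")
    if hasattr(source, "read"):
        data = source.read()
        return data.decode("utf-8", errors="replace") if isinstance(data, bytes) else data
    return str(source)


def _source_file_ref(path, fmt: str) -> FileReference | None:
    if not isinstance(path, (str, Path)) or "\n" in str(path):
        return None
    p = Path(path)
    if not p.is_file():
        return None
    return FileReference(uid=p.name, path=str(p), format=fmt, role="output",
                         size=p.stat().st_size)


# ---------------------------------------------------------------------------
# keyed KEY = value blocks (MDLOG / QMLOG)


def _parse_keyed(text: str, magic: str):
    lines = text.splitlines()
    if not lines or not lines[0].startswith(magic):
        raise ParseError(f"missing {magic} header", line=1)
    values: dict[str, str] = {}
    footer: str | None = None
    for number, line in enumerate(lines[1:], start=2):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("FOOTER:"):
            footer = stripped[len("FOOTER:"):].strip()
            continue
        if "=" not in stripped:
            raise ParseError(f"malformed line {stripped!r}", line=number)
        key, _, value = stripped.partition("=")
        values[key.strip()] = value.strip()
    return values, footer


def _quantity(values: dict, key: str, unit: str | None) -> Quantity | None:
    if key not in values:
        return None
    return Quantity(value=float(values[key]), unit=unit)


def _flag(values: dict, key: str) -> bool | None:
    if key not in values:
        return None
    return values[key].lower() in ("true", "1", "yes")


def _software(values: dict) -> Software | None:
    if not any(k in values for k in ("SOFTWARE", "VERSION", "EXECUTABLE")):
        return None
    return Software(name=values.get("SOFTWARE"), version=values.get("VERSION"),
                    executable=values.get("EXECUTABLE"))


def _environment(values: dict) -> ComputingEnvironment | None:
    keys = ("OS", "CPU_ARCH", "GPU_ARCH", "MACHINE_ARCH", "MACHINE_NAME")
    if not any(k in values for k in keys):
        return None
    return ComputingEnvironment(
        os=values.get("OS"),
        cpu_architecture=values.get("CPU_ARCH"),
        gpu_architecture=values.get("GPU_ARCH"),
        machine_architecture=values.get("MACHINE_ARCH"),
        machine_name=values.get("MACHINE_NAME"),
    )


def _execution(values: dict, footer: str | None) -> TaskExecution:
    return TaskExecution(
        start=values.get("START"),
        end=values.get("END"),
        elapsed_seconds=(float(values["ELAPSED_SECONDS"])
                         if "ELAPSED_SECONDS" in values else None),
        termination_status=footer.lower() if footer else "incomplete",
    )


def _conditions(values: dict) -> SimulatedConditions | None:
    pressure = _quantity(values, "REF_PRESSURE_BAR", "bar")
    temperature = _quantity(values, "REF_TEMPERATURE_K", "K")
    if pressure is None and temperature is None:
        return None
    return SimulatedConditions(reference_pressure=pressure,
                               reference_temperature=temperature)


def parse_md_output(source) -> MDTaskRecord:
    """Parse one MDLOG file into an MD task record.

    The record mirrors exactly what the file states; a missing footer
    yields termination status "incomplete".
    """
    text = _read_text(source)
    values, footer = _parse_keyed(text, "%MDLOG")
    if "TASK_KIND" not in values:
        raise ParseError("MDLOG file does not declare TASK_KIND")
    task_kind = values["TASK_KIND"]
    if task_kind not in ("minimization", "md"):
        raise ParseError(f"unknown TASK_KIND {task_kind!r}")

    params = MDParameterSet(
        force_fields=[ForceField(n.strip())
                      for n in values.get("FORCE_FIELDS", "").split(";")
                      if n.strip()],
        ensemble=values.get("ENSEMBLE"),
        electrostatics_model=values.get("ELECTROSTATICS"),
        collision_frequency=_quantity(values, "COLLISION_FREQUENCY_PS", "1/ps"),
        n_steps=int(values["N_STEPS"]) if "N_STEPS" in values else None,
        step_length=_quantity(values, "STEP_LENGTH_PS", "ps"),
    )
    if "THERMOSTAT" in values:
        params.thermostat = Thermostat(
            implementation_name=values["THERMOSTAT"],
            time_constant=_quantity(values, "THERMOSTAT_TIME_CONSTANT_PS", "ps"),
        )
    if "BAROSTAT" in values:
        params.barostat = Barostat(
            implementation_name=values["BAROSTAT"],
            time_constant=_quantity(values, "BAROSTAT_TIME_CONSTANT_PS", "ps"),
        )
    for spec in values.get("CONSTRAINTS", "").split(";"):
        if spec.strip():
            algorithm, _, target = spec.strip().partition(":")
            params.constraints.append(Constraint(algorithm, target or "all"))
    for spec in values.get("RESTRAINTS", "").split(";"):
        if spec.strip():
            prop, _, target = spec.strip().partition(":")
            params.restraints.append(Restraint(prop, target or "all"))

    return MDTaskRecord(
        task_kind=task_kind,
        run_context=values.get("RUN_CONTEXT"),
        parameters=params,
        conditions=_conditions(values),
        software=_software(values),
        environment=_environment(values),
        execution=_execution(values, footer),
        boundary_conditions=values.get("BOUNDARY_CONDITIONS"),
        solvent_type=values.get("SOLVENT_TYPE"),
        calculations=[c.strip() for c in values.get("CALCULATION", "").split(";")
                      if c.strip()],
        system_name=values.get("SYSTEM"),
        copy_index=int(values["COPY"]) if "COPY" in values else None,
        source_file=_source_file_ref(source, "MDLOG"),
    )


def parse_qm_output(source) -> QMTaskRecord:
    """Parse one QMLOG file into a QM task record.

    Method and basis-set names are captured verbatim — an unmapped basis
    set such as "LANL2DZ" is retained as a specific name with no
    dictionary link.
    """
    text = _read_text(source)
    values, footer = _parse_keyed(text, "%QMLOG")
    params = QMParameterSet(
        method=MethodSpec(values["METHOD"]) if "METHOD" in values else None,
        basis_set_name=values.get("BASIS_SET"),
        frozen_core=_flag(values, "FROZEN_CORE"),
        pseudopotentials=_flag(values, "PSEUDOPOTENTIALS"),
        plane_wave_cutoff=_quantity(values, "PLANE_WAVE_CUTOFF_EV", "eV"),
        convergence_flag=_flag(values, "CONVERGED"),
        convergence_criteria=values.get("CONVERGENCE_CRITERIA"),
    )
    return QMTaskRecord(
        parameters=params,
        conditions=_conditions(values),
        software=_software(values),
        environment=_environment(values),
        execution=_execution(values, footer),
        boundary_conditions=values.get("BOUNDARY_CONDITIONS"),
        solvent_type=values.get("SOLVENT_TYPE"),
        calculations=[c.strip() for c in values.get("CALCULATION", "").split(";")
                      if c.strip()],
        system_name=values.get("SYSTEM"),
        source_file=_source_file_ref(source, "QMLOG"),
    )


# ---------------------------------------------------------------------------
# topology


def parse_topology(source) -> MolecularSystem:
    """Parse a SIMTOP file into a molecular system.

    Molecules are stored as occurrence counts: a water block yields one
    hydrogen entry with count 2 and one oxygen entry with count 1, plus
    the count of water molecules in the system.  Declared counts that
    disagree with the listed content raise a parse error.
    """
    text = _read_text(source)
    lines = text.splitlines()
    if not lines or not lines[0].startswith("%SIMTOP"):
        raise ParseError("missing %SIMTOP header", line=1)

    sections: list[tuple[str, dict, int]] = []
    current: dict | None = None
    for number, line in enumerate(lines[1:], start=2):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("%SECTION"):
            name = stripped[len("%SECTION"):].strip()
            if not name:
                raise ParseError("unnamed %SECTION", line=number)
            current = {}
            sections.append((name, current, number))
            continue
        if current is None:
            raise ParseError(f"data outside a %SECTION: {stripped!r}",
                             line=number)
        if "=" not in stripped:
            raise ParseError(f"malformed line {stripped!r}", line=number)
        key, _, value = stripped.partition("=")
        current[key.strip()] = value.strip()

    system_vals: dict = {}
    molecules: list[Molecule] = []
    for name, vals, number in sections:
        if name == "SYSTEM":
            system_vals = vals
        elif name == "MOLECULE":
            molecules.append(_parse_molecule(vals, number))
        else:
            raise ParseError(f"unknown section {name!r}", line=number)

    declared = system_vals.get("MOLECULE_TYPES")
    if declared is not None and int(declared) != len(molecules):
        raise ParseError(
            f"SYSTEM declares {declared} molecule types but {len(molecules)} "
            "MOLECULE sections are listed"
        )
    system_name = system_vals.get("NAME", "unnamed system")
    system = MolecularSystem(
        id=deterministic_id("system", system_name,
                            *[m.name for m in molecules]),
        name=system_name,
        molecules=molecules,
        topology_files=[ref for ref in [_source_file_ref(source, "SIMTOP")]
                        if ref is not None],
    )
    for ref in system.topology_files:
        ref.role = "topology"
    return system


def _parse_molecule(vals: dict, section_line: int) -> Molecule:
    residues = [r.strip() for r in vals.get("RESIDUES", "").split(",")
                if r.strip()]
    declared_res = vals.get("N_RESIDUES")
    if declared_res is not None and int(declared_res) != len(residues):
        raise ParseError(
            f"molecule declares {declared_res} residues but lists "
            f"{len(residues)}", line=section_line,
        )
    atoms = []
    for spec in vals.get("ATOMS", "").split(","):
        if not spec.strip():
            continue
        element, _, count = spec.strip().partition(":")
        if not count:
            raise ParseError(f"malformed atom occurrence {spec!r}",
                             line=section_line)
        atoms.append(AtomOccurrence(element=element, count=int(count)))
    res_counts: dict[str, int] = {}
    for r in residues:
        res_counts[r] = res_counts.get(r, 0) + 1
    return Molecule(
        name=vals.get("NAME", "unnamed"),
        count=int(vals.get("COUNT", "1")),
        molecule_type=vals.get("TYPE"),
        residue_occurrences=[ResidueOccurrence(name=r, count=c)
                             for r, c in res_counts.items()],
        atom_occurrences=atoms,
        specific_chain=residues,
    )


# ---------------------------------------------------------------------------
# executable names and sequences


def parse_executable_name(name: str) -> SoftwareBuildInfo:
    """Split an executable name into product, revision and architecture.

    Recognizes the ``<ARCH>-<PRODUCT>Rev<REVISION>`` pattern used by
    Gaussian builds and a short list of known engine executables;
    anything else degrades gracefully to the raw string.
    """
    if not name or not name.strip():
        raise UsageError("executable name must be non-empty")
    match = _EXECUTABLE_PATTERN.match(name.strip())
    if match:
        return SoftwareBuildInfo(
            raw=name,
            product=match.group("product"),
            revision=match.group("revision"),
            target_architecture=match.group("arch"),
        )
    if name.strip().upper() in KNOWN_ENGINE_EXECUTABLES:
        return SoftwareBuildInfo(raw=name, product=name.strip().upper())
    return SoftwareBuildInfo(raw=name)


UNKNOWN_RESIDUE_CODE = "X"


def normalize_sequence(
    specific_residues: list[str],
    residue_dictionary: Dictionary | None = None,
) -> str:
    """Re-express a residue chain in standard one-letter codes.

    Residues absent from the residue dictionary (or without a one-letter
    code, e.g. water) become the placeholder character "X"; the specific
    chain is always preserved separately on the molecule.
    """
    if not specific_residues:
        raise UsageError("residue list must be non-empty")
    if residue_dictionary is None:
        residue_dictionary = load_packaged_dictionaries()["residue"]
    by_term = {e.term.upper(): e for e in residue_dictionary}
    out = []
    for residue in specific_residues:
        entry = by_term.get(residue.strip().upper())
        code = entry.extras.get("CODE") if entry is not None else None
        out.append(code if code else UNKNOWN_RESIDUE_CODE)
    return "".join(out)
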