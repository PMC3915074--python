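"""Flatten experiments into attribute-value-unit triplets and query them.

Every annotation is an AVU triplet — attribute, value, optional unit —
attached to a subject (an experiment, task, molecular system or file).
Flattening walks the experiment tree and emits one triplet per mapped
field that carries a value, plus *derived* triplets computed through the
dictionaries: the force-field name "AMBER FF99SB" is stored and its type
"classical" inferred; the QM method "MP2" yields its class
"Møller-Plesset" and family "ab initio"; residue chains gain their
normalized one-letter form.

Attribute names are qualified as ``<Element>/<attribute>`` following the
flattening map below (version 1), keyed to the packaged CDE catalogue so
completeness of an annotation set can be scored against the recommended
attributes.  Subjects are strings of the form ``kind:id`` (e.g.
``file:md1.out``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dictionaries import (
    DictionarySet,
    classify_method,
    lookup_term,
    resolve_link,
)
from .errors import UsageError
from .model import Experiment, MDParameterSet, QMParameterSet, Quantity
from .parsers import normalize_sequence

#: Version tag of the field -> attribute flattening map.
FLATTEN_MAP_VERSION = "1"

COMPARATORS = ("=", "contains")


@dataclass(frozen=True)
class AVUTriplet:
    attribute: str
    value: str
    unit: str | None = None
    subject: str = ""
    standard: bool = False  # recognized by the CDE catalogue / flatten map
    derived: bool = False  # inferred through a dictionary, not stored data


@dataclass
class TripletStore:
    """A flat collection of AVU triplets with linear-scan-equivalent queries."""

    triplets: list[AVUTriplet] = field(default_factory=list)
    catalog: object | None = None  # CDECatalog, optional


def canonical_value(value) -> str:
    """Serialize values uniformly: trimmed strings, plain numbers."""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value) if value != int(value) else str(int(value))
    return str(value).strip()


def _emit(out, subject, attribute, value, unit=None, derived=False):
    if value is None:
        return
    text = canonical_value(value)
    if text == "":
        return
    out.append(AVUTriplet(attribute=attribute, value=text, unit=unit,
                          subject=subject, standard=True, derived=derived))


def _emit_quantity(out, subject, attribute, quantity: Quantity | None):
    if quantity is not None:
        _emit(out, subject, attribute, quantity.value, unit=quantity.unit)


def _force_field_type(name: str, dictionaries: DictionarySet) -> str | None:
    ff = dictionaries.get("force_field")
    if ff is None:
        return None
    entry = lookup_term(ff, name)
    if entry is None or "TYPE_ID" not in entry.links:
        return None
    return resolve_link(entry, "TYPE_ID", dictionaries).term


def _flatten_md_parameters(out, subject, params: MDParameterSet,
                           dictionaries: DictionarySet):
    for ff in params.force_fields:
        _emit(out, subject, "Force field/name", ff.specific_name)
        kind = _force_field_type(ff.specific_name, dictionaries)
        if kind is not None:
            _emit(out, subject, "Force field/force field type", kind,
                  derived=True)
    if params.barostat is not None:
        _emit(out, subject, "Barostat/implementation name",
              params.barostat.implementation_name)
        _emit_quantity(out, subject, "Barostat/time constant",
                       params.barostat.time_constant)
    if params.thermostat is not None:
        _emit(out, subject, "Thermostat/implementation name",
              params.thermostat.implementation_name)
        _emit_quantity(out, subject, "Thermostat/time constant",
                       params.thermostat.time_constant)
    _emit(out, subject, "Ensemble/ensemble type", params.ensemble)
    _emit(out, subject, "MD parameter set/electrostatics model",
          params.electrostatics_model)
    _emit(out, subject, "MD parameter set/number of steps", params.n_steps)
    _emit_quantity(out, subject, "MD parameter set/step length",
                   params.step_length)
    _emit_quantity(out, subject, "MD parameter set/collision frequency",
                   params.collision_frequency)
    for constraint in params.constraints:
        _emit(out, subject, "Constraint/algorithm", constraint.algorithm)
        _emit(out, subject, "Constraint/target", constraint.target)
    for restraint in params.restraints:
        _emit(out, subject, "Restraint/restrained property",
              restraint.restrained_property)
        _emit(out, subject, "Restraint/target", restraint.target)


def _flatten_qm_parameters(out, subject, params: QMParameterSet,
                           dictionaries: DictionarySet):
    if params.method is not None:
        _emit(out, subject, "QM method/method name",
              params.method.specific_name)
        classification = classify_method(params.method.specific_name,
                                         dictionaries)
        if classification.method_class is not None:
            _emit(out, subject, "QM method/method class",
                  classification.method_class.term, derived=True)
        if classification.method_family is not None:
            _emit(out, subject, "QM method/method family",
                  classification.method_family.term, derived=True)
    if params.basis_set_name is not None:
        _emit(out, subject, "Basis set/name", params.basis_set_name)
        basis = dictionaries.get("basis_set")
        entry = lookup_term(basis, params.basis_set_name) if basis else None
        if entry is not None and "TYPE" in entry.extras:
            _emit(out, subject, "Basis set/basis set type",
                  entry.extras["TYPE"], derived=True)
    _emit(out, subject, "QM parameter set/frozen core flag",
          params.frozen_core)
    _emit(out, subject, "QM parameter set/pseudopotentials flag",
          params.pseudopotentials)
    _emit_quantity(out, subject, "QM parameter set/plane wave cutoff",
                   params.plane_wave_cutoff)
    _emit(out, subject, "Convergence/convergence flag",
          params.convergence_flag)
    _emit(out, subject, "Convergence/convergence criteria",
          params.convergence_criteria)


def flatten_to_triplets(experiment: Experiment,
                        dictionaries: DictionarySet) -> list[AVUTriplet]:
    """Flatten an experiment into AVU triplets (deterministic, idempotent).

    An empty experiment yields only its identity triplets.
    """
    out: list[AVUTriplet] = []
    subject = f"experiment:{experiment.id}"
    _emit(out, subject, "Experiment/id", experiment.id)
    _emit(out, subject, "Experiment/name", experiment.name)
    _emit(out, subject, "Experiment/role", experiment.role)
    if experiment.author is not None:
        _emit(out, subject, "Author/name", experiment.author.name)
        _emit(out, subject, "Author/institution",
              experiment.author.institution)
        _emit(out, subject, "Author/contact", experiment.author.contact)
    for citation in experiment.citations:
        _emit(out, subject, "Citation/citation", citation.text)
    for grant in experiment.grants:
        _emit(out, subject, "Grant/agency", grant.agency)
        _emit(out, subject, "Grant/grant number", grant.number)
    for xattr in experiment.extended:
        out.append(AVUTriplet(attribute=xattr.attribute, value=xattr.value,
                              unit=xattr.unit, subject=subject,
                              standard=False))

    residue_dict = dictionaries.get("residue")
    for system in experiment.all_systems():
        ssubj = f"system:{system.id}"
        _emit(out, ssubj, "Molecular system/name", system.name)
        for molecule in system.molecules:
            _emit(out, ssubj, "Molecule/name", molecule.name)
            _emit(out, ssubj, "Molecule/count", molecule.count)
            _emit(out, ssubj, "Molecule/molecule type",
                  molecule.molecule_type)
            for occ in molecule.residue_occurrences:
                _emit(out, ssubj, "Residue occurrence/residue name", occ.name)
            for occ in molecule.atom_occurrences:
                _emit(out, ssubj, "Atom occurrence/element", occ.element)
            if molecule.specific_chain:
                _emit(out, ssubj, "Biomolecule/specific chain",
                      "-".join(molecule.specific_chain))
                _emit(out, ssubj, "Biomolecule/normalized chain",
                      normalize_sequence(molecule.specific_chain,
                                         residue_dict),
                      derived=True)
        for ref in system.topology_files:
            _flatten_file(out, ref)

    for task in experiment.all_tasks():
        tsubj = f"task:{task.id}"
        _emit(out, tsubj, "Experiment task/method name", task.method_name)
        _emit(out, tsubj, "Experiment task/task description",
              task.description)
        _emit(out, tsubj, "Boundary conditions/boundary type",
              task.boundary_conditions)
        _emit(out, tsubj, "Solvent/solvent type", task.solvent_type)
        for calculation in task.calculations:
            _emit(out, tsubj, "Calculation/calculation type", calculation)
        if task.conditions is not None:
            _emit_quantity(out, tsubj,
                           "Simulated conditions/reference pressure",
                           task.conditions.reference_pressure)
            _emit_quantity(out, tsubj,
                           "Simulated conditions/reference temperature",
                           task.conditions.reference_temperature)
        if task.software is not None:
            _emit(out, tsubj, "Software/name", task.software.name)
            _emit(out, tsubj, "Software/version", task.software.version)
            _emit(out, tsubj, "Software/executable", task.software.executable)
        if task.environment is not None:
            env = task.environment
            _emit(out, tsubj, "Computing environment/operating system", env.os)
            _emit(out, tsubj, "Computing environment/CPU architecture",
                  env.cpu_architecture)
            _emit(out, tsubj, "Computing environment/GPU architecture",
                  env.gpu_architecture)
            _emit(out, tsubj, "Computing environment/machine architecture",
                  env.machine_architecture)
            _emit(out, tsubj, "Computing environment/machine name",
                  env.machine_name)
        if task.execution is not None:
            exe = task.execution
            _emit(out, tsubj, "Task execution/start timestamp", exe.start)
            _emit(out, tsubj, "Task execution/end timestamp", exe.end)
            _emit(out, tsubj, "Task execution/execution time",
                  exe.elapsed_seconds, unit="s")
            _emit(out, tsubj, "Task execution/termination status",
                  exe.termination_status)
        for params in task.parameter_sets:
            if isinstance(params, MDParameterSet):
                _flatten_md_parameters(out, tsubj, params, dictionaries)
            elif isinstance(params, QMParameterSet):
                _flatten_qm_parameters(out, tsubj, params, dictionaries)
            else:
                _emit(out, tsubj, "QM/MM boundary/boundary treatment",
                      params.boundary_treatment)
        for xattr in task.extended:
            out.append(AVUTriplet(attribute=xattr.attribute,
                                  value=xattr.value, unit=xattr.unit,
                                  subject=tsubj, standard=False))
        for ref in task.files:
            _flatten_file(out, ref)
    return out


def _flatten_file(out, ref):
    fsubj = f"file:{ref.uid}"
    _emit(out, fsubj, "File/format", ref.format)
    _emit(out, fsubj, "File/role", ref.role)
    _emit(out, fsubj, "File/size", ref.size, unit="bytes")


# ---------------------------------------------------------------------------
# queries and tagging


def _predicate_matches(triplet: AVUTriplet, attribute: str, comparator: str,
                       value: str) -> bool:
    if triplet.attribute != attribute:
        return False
    if comparator == "=":
        return triplet.value == value
    if comparator == "contains":
        return value.casefold() in triplet.value.casefold()
    raise UsageError(f"unknown comparator {comparator!r}")


def query_index(store: TripletStore, predicates) -> list[str]:
    """Subjects satisfying the conjunction of (attribute, comparator, value)
    predicates; equivalent to a linear scan of the store."""
    predicates = list(predicates)
    if not predicates:
        raise UsageError("at least one predicate is required")
    for _, comparator, _ in predicates:
        if comparator not in COMPARATORS:
            raise UsageError(f"unknown comparator {comparator!r}")
    result: list[str] | None = None
    for attribute, comparator, value in predicates:
        matched = []
        seen = set()
        for triplet in store.triplets:
            if (_predicate_matches(triplet, attribute, comparator, value)
                    and triplet.subject not in seen):
                seen.add(triplet.subject)
                matched.append(triplet.subject)
        if result is None:
            result = matched
        else:
            keep = set(matched)
            result = [s for s in result if s in keep]
    return result or []


def tag_subject(store: TripletStore, subject: str, attribute: str,
                value, unit: str | None = None) -> TripletStore:
    """Attach a user annotation; catalogue-recognized attributes are
    flagged standard, anything else user-specific (never rejected)."""
    if not attribute or not attribute.strip():
        raise UsageError("attribute must be non-empty")
    standard = False
    if store.catalog is not None:
        standard = store.catalog.knows_attribute(attribute)
    store.triplets.append(
        AVUTriplet(attribute=attribute, value=canonical_value(value),
                   unit=unit, subject=subject, standard=standard)
    )
    return store
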