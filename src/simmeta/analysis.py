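"""Descriptors for derived analysis datasets.

Analysis output (RMSD series, covariance matrices, ...) is described —
never computed — by the scheme self-describing array formats use:
named *dimensions* with sizes, and *variables* that reference zero or
more dimensions (zero dimensions is a scalar such as an average RMSD,
one is an array such as an RMSD time series, two is a matrix such as a
coordinate covariance).  A *provenance record* states how the data was
made: analysis method name and description, the program and version,
the exact command, an execution timestamp, and the optional reference
system (self, experimental, or another simulated structure).

Optional *filters* narrow the scope: file dependencies (which also
drive currency checking — an analysis whose input trajectory is newer
than the artifact needs an update), a time filter, and a space filter
kept as the program's own atom-selection string with a program tag,
deliberately untranslated.

Descriptors persist as JSON sidecar documents next to the analysis
file and reload losslessly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ShapeError, UsageError


@dataclass
class ProvenanceRecord:
    method_name: str
    method_description: str = ""
    program_name: str = ""
    program_version: str | None = None
    command: str | None = None
    input_path: str | None = None
    timestamp: str | None = None
    reference_system: str | None = None  # self | experimental | other simulated structure


@dataclass
class SpaceFilter:
    """An atom selection in the analysis program's own syntax.

    Selections are not translated to a common representation; the
    program tag says whose syntax the string is in.
    """

    selection: str
    program: str | None = None


@dataclass
class AnalysisVariable:
    name: str
    value_type: str  # integer | float | string
    dimensions: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    unit: str | None = None

    @property
    def rank(self) -> int:
        return len(self.dimensions)


@dataclass
class AnalysisDataDescriptor:
    dimensions: dict[str, int] = field(default_factory=dict)
    variables: list[AnalysisVariable] = field(default_factory=list)
    provenance: ProvenanceRecord | None = None
    artifact_path: str | None = None
    file_dependencies: list[str] = field(default_factory=list)
    time_filter: str | None = None
    space_filter: SpaceFilter | None = None


def _shape_of(values) -> tuple[int, ...]:
    """Shape of a nested-list dataset; ragged nesting is a shape error."""
    if isinstance(values, (str, bytes)):
        return ()
    try:
        iter(values)
    except TypeError:
        return ()
    rows = list(values)
    if not rows:
        return (0,)
    inner_shapes = {_shape_of(row) for row in rows}
    if len(inner_shapes) != 1:
        raise ShapeError(f"ragged dataset: inner shapes {sorted(inner_shapes)}")
    return (len(rows),) + inner_shapes.pop()


def _value_type(values) -> str:
    flat = values
    while True:
        if isinstance(flat, (str, bytes)):
            return "string"
        try:
            flat = next(iter(flat))
        except TypeError:
            break
        except StopIteration:
            return "float"
    if isinstance(flat, bool):
        return "string"
    if isinstance(flat, int):
        return "integer"
    if isinstance(flat, float):
        return "float"
    return "string"


def describe_variables(datasets: dict) -> AnalysisDataDescriptor:
    """Describe named value collections by dimensionality.

    A scalar yields a 0-dimension variable, a sequence one dimension, a
    nested table two, and so on; dimension sizes are recorded under
    generated names (``<variable>_d<axis>``).
    """
    if not datasets:
        raise UsageError("at least one dataset is required")
    descriptor = AnalysisDataDescriptor()
    for name, values in datasets.items():
        shape = _shape_of(values)
        dims = []
        for axis, size in enumerate(shape):
            dim_name = f"{name}_d{axis}"
            descriptor.dimensions[dim_name] = size
            dims.append(dim_name)
        descriptor.variables.append(
            AnalysisVariable(name=name, value_type=_value_type(values),
                             dimensions=dims)
        )
    return descriptor


def describe_file(path, delimiter: str | None = None) -> AnalysisDataDescriptor:
    """Infer a descriptor from a comma- or tab-delimited analysis file."""
    frame = pd.read_csv(path, sep=delimiter, engine="python")
    descriptor = AnalysisDataDescriptor(artifact_path=str(path))
    descriptor.dimensions["rows"] = len(frame)
    for column in frame.columns:
        kind = frame[column].dtype.kind
        value_type = ("integer" if kind in "iu"
                      else "float" if kind == "f" else "string")
        descriptor.variables.append(
            AnalysisVariable(name=str(column), value_type=value_type,
                             dimensions=["rows"])
        )
    return descriptor


def build_provenance(
    method: str,
    description: str = "",
    program: tuple[str, str | None] | str = "",
    command: str | None = None,
    inputs: list[str] | None = None,
    timestamp: str | None = None,
    reference: str | None = None,
) -> ProvenanceRecord:
    """Build a provenance record; method and program names are mandatory."""
    if not method or not method.strip():
        raise UsageError("analysis method name must be non-empty")
    if isinstance(program, str):
        program_name, program_version = program, None
    else:
        program_name, program_version = program
    if not program_name or not program_name.strip():
        raise UsageError("program name must be non-empty")
    return ProvenanceRecord(
        method_name=method,
        method_description=description,
        program_name=program_name,
        program_version=program_version,
        command=command,
        input_path=inputs[0] if inputs else None,
        timestamp=timestamp,
        reference_system=reference,
    )


def check_currency(descriptor: AnalysisDataDescriptor, timestamps) -> str:
    """Is the analysis artifact current with respect to its dependencies?

    ``timestamps`` maps paths (the artifact and its file dependencies) to
    modification times in seconds.  Comparison is at whole-second
    resolution with ties counted as current.  Any *known* dependency
    newer than the artifact means "needs_update" regardless of the rest;
    otherwise a single unavailable timestamp means "unknown".
    """
    if not descriptor.file_dependencies:
        raise UsageError("descriptor lists no file dependencies")
    artifact_time = (timestamps.get(descriptor.artifact_path)
                     if descriptor.artifact_path else None)
    unknown = artifact_time is None
    for dependency in descriptor.file_dependencies:
        dep_time = timestamps.get(dependency)
        if dep_time is None:
            unknown = True
        elif artifact_time is not None and int(dep_time) > int(artifact_time):
            return "needs_update"
    return "unknown" if unknown else "current"


# ---------------------------------------------------------------------------
# sidecar persistence


def descriptor_to_json(descriptor: AnalysisDataDescriptor) -> str:
    return json.dumps(asdict(descriptor), indent=2, sort_keys=True)


def descriptor_from_json(text: str) -> AnalysisDataDescriptor:
    data = json.loads(text)
    provenance = (ProvenanceRecord(**data["provenance"])
                  if data.get("provenance") else None)
    space = (SpaceFilter(**data["space_filter"])
             if data.get("space_filter") else None)
    return AnalysisDataDescriptor(
        dimensions=data.get("dimensions", {}),
        variables=[AnalysisVariable(**v) for v in data.get("variables", [])],
        provenance=provenance,
        artifact_path=data.get("artifact_path"),
        file_dependencies=data.get("file_dependencies", []),
        time_filter=data.get("time_filter"),
        space_filter=space,
    )


def sidecar_path(artifact_path) -> Path:
    return Path(str(artifact_path) + ".meta.json")


def save_descriptor(descriptor: AnalysisDataDescriptor, path=None) -> Path:
    if path is None:
        if not descriptor.artifact_path:
            raise UsageError("no artifact path to place the sidecar next to")
        path = sidecar_path(descriptor.artifact_path)
    Path(path).write_text(descriptor_to_json(descriptor), encoding="utf-8")
    return Path(path)


def load_descriptor(path) -> AnalysisDataDescriptor:
    return descriptor_from_json(Path(path).read_text(encoding="utf-8"))
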