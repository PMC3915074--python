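"""Exception hierarchy shared by all simmeta modules."""


class SimmetaError(Exception):
    """Base class for all errors raised by simmeta."""


class UsageError(SimmetaError):
    """A caller violated an operation's contract (bad argument, empty input)."""


class SchemaError(SimmetaError):
    """A tabular source is missing mandatory columns or is structurally invalid."""


class DictionaryLoadError(SimmetaError):
    """A dictionary CSV could not be loaded (e.g. duplicate identifiers)."""


class ReferentialIntegrityError(SimmetaError):
    """A cross-dictionary link points at an identifier that does not exist."""


class ParseError(SimmetaError):
    """A simulation file could not be parsed.

    Carries the 1-based line number at which parsing failed, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AssemblyError(SimmetaError):
    """Parsed records could not be assembled into a consistent experiment."""


class ShapeError(SimmetaError):
    """An analysis dataset has an inconsistent (ragged) shape."""


class CycleError(SimmetaError):
    """Adding a dependency edge would create a cycle."""


class SerializationError(SimmetaError):
    """An experiment document could not be written or read back."""
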