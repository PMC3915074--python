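"""Controlled-vocabulary dictionaries for biomolecular simulation metadata.

Each dictionary is defined by a CSV file with at least three mandatory
columns — ``ID``, ``TERM``, ``DESCRIPTION`` — plus optional extra columns.
Extra columns either carry scalar attributes (e.g. a citation, a boolean
flag) or link to entries of another dictionary (foreign keys named
``<TARGET>_ID``).  The packaged set covers force fields and their types,
QM methods with their class/family hierarchy, basis sets, thermostats,
barostats, ensembles, constraint algorithms, electrostatics models,
enhanced-sampling and analysis methods, residues, elements and their
families, functional groups, software packages, file formats and
calculation types.

Terms are matched case-insensitively with whitespace normalization, and an
inverted index supports exact, prefix and token-boundary searches with a
deterministic ranking (exact > prefix > token, ties broken by term order).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

from .errors import (
    DictionaryLoadError,
    ReferentialIntegrityError,
    SchemaError,
    UsageError,
)

MANDATORY_COLUMNS = ("ID", "TERM", "DESCRIPTION")

#: Link columns whose target dictionary cannot be inferred from the column
#: name alone.  Everything else follows the ``<TARGET>_ID`` convention.
LINK_TARGET_OVERRIDES: dict[tuple[str, str], str] = {
    ("force_field", "TYPE_ID"): "force_field_type",
    ("qm_method", "CLASS_ID"): "qm_method_class",
    ("qm_method_class", "FAMILY_ID"): "qm_method_family",
    ("element", "FAMILY_ID"): "element_family",
}

#: Names of the packaged dictionaries.
PACKAGED_DICTIONARIES = (
    "force_field",
    "force_field_type",
    "qm_method",
    "qm_method_class",
    "qm_method_family",
    "computational_method",
    "basis_set",
    "barostat",
    "thermostat",
    "ensemble",
    "constraint_algorithm",
    "electrostatics",
    "enhanced_sampling",
    "md_analysis_method",
    "residue",
    "element",
    "element_family",
    "functional_group",
    "software",
    "file_format",
    "calculation_type",
)


@dataclass(frozen=True)
class ColumnSpec:
    """One column of a dictionary CSV.

    kind is one of ``mandatory``, ``scalar``, ``bool`` or ``link``; for a
    link column, ``target`` names the dictionary the IDs refer to.
    """

    name: str
    kind: str
    target: str | None = None


@dataclass(frozen=True)
class LinkRef:
    """An unresolved reference to an entry of another dictionary."""

    target_dictionary: str
    target_id: str


@dataclass
class DictionaryEntry:
    id: str
    term: str
    description: str
    citation: str | None = None
    extras: dict[str, Union[str, bool]] = field(default_factory=dict)
    links: dict[str, LinkRef] = field(default_factory=dict)


@dataclass
class Dictionary:
    """A single controlled vocabulary keyed by entry id."""

    name: str
    schema: tuple[ColumnSpec, ...]
    entries: dict[str, DictionaryEntry]

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self):
        return len(self.entries)

    def get(self, entry_id: str) -> DictionaryEntry | None:
        return self.entries.get(entry_id)


DictionarySet = Mapping[str, Dictionary]


def normalize_term(text: str) -> str:
    """Case-fold and collapse internal whitespace for matching."""
    return re.sub(r"\s+", " ", text.strip()).casefold()


def _infer_schema(name: str, header: list[str]) -> tuple[ColumnSpec, ...]:
    for col in MANDATORY_COLUMNS:
        if col not in header:
            raise SchemaError(
                f"dictionary {name!r}: missing mandatory column {col!r}"
            )
    specs: list[ColumnSpec] = []
    for col in header:
        if col in MANDATORY_COLUMNS:
            specs.append(ColumnSpec(col, "mandatory"))
        elif (name, col) in LINK_TARGET_OVERRIDES:
            specs.append(ColumnSpec(col, "link", LINK_TARGET_OVERRIDES[(name, col)]))
        elif col.endswith("_ID"):
            specs.append(ColumnSpec(col, "link", col[:-3].lower()))
        elif col.startswith("IS_") or col.endswith("_FLAG"):
            specs.append(ColumnSpec(col, "bool"))
        else:
            specs.append(ColumnSpec(col, "scalar"))
    return tuple(specs)


def load_dictionary(
    source,
    name: str | None = None,
    schema: Iterable[ColumnSpec] | None = None,
) -> Dictionary:
    """Load one dictionary from a CSV source (path or open text stream).

    The source must have a single header row with at least the three
    mandatory columns.  Extra columns are preserved as scalar extras,
    boolean flags, or links, in schema order.  Duplicate entry ids and
    empty terms are load errors.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if name is None:
            name = path.stem
        with open(path, newline="", encoding="utf-8") as fh:
            return _load_rows(fh, name, schema)
    if name is None:
        raise UsageError("a name is required when loading from a stream")
    if isinstance(source, bytes):
        source = source.decode("utf-8")
    if isinstance(source, str):
        source = io.StringIO(source)
    return _load_rows(source, name, schema)


def _load_rows(fh, name: str, schema) -> Dictionary:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError(f"dictionary {name!r}: empty source") from None
    specs = tuple(schema) if schema is not None else _infer_schema(name, header)
    if {s.name for s in specs} != set(header):
        raise SchemaError(
            f"dictionary {name!r}: schema columns do not match the header"
        )
    by_name = {s.name: s for s in specs}
    entries: dict[str, DictionaryEntry] = {}
    for row in reader:
        if not row or all(not cell.strip() for cell in row):
            continue
        values = dict(zip(header, row))
        entry_id = values.get("ID", "").strip()
        term = values.get("TERM", "").strip()
        if not entry_id:
            raise DictionaryLoadError(f"dictionary {name!r}: entry with empty ID")
        if not term:
            raise DictionaryLoadError(
                f"dictionary {name!r}: entry {entry_id!r} has an empty term"
            )
        if entry_id in entries:
            raise DictionaryLoadError(
                f"dictionary {name!r}: duplicate id {entry_id!r}"
            )
        entry = DictionaryEntry(
            id=entry_id,
            term=term,
            description=values.get("DESCRIPTION", "").strip(),
        )
        for col, raw in values.items():
            spec = by_name[col]
            raw = raw.strip()
            if spec.kind == "mandatory":
                continue
            if col == "CITATION":
                entry.citation = raw or None
            elif spec.kind == "link":
                if raw:
                    entry.links[col] = LinkRef(spec.target, raw)
            elif spec.kind == "bool":
                entry.extras[col] = raw.lower() in ("true", "1", "yes")
            else:
                if raw:
                    entry.extras[col] = raw
        entries[entry_id] = entry
    return Dictionary(name=name, schema=specs, entries=entries)


def _packaged_dictionary_dir():
    return resources.files("simmeta").joinpath("data", "dictionaries")


def load_packaged_dictionaries() -> dict[str, Dictionary]:
    """Load the dictionary set shipped with the package."""
    root = _packaged_dictionary_dir()
    out: dict[str, Dictionary] = {}
    for name in PACKAGED_DICTIONARIES:
        with root.joinpath(f"{name}.csv").open(encoding="utf-8", newline="") as fh:
            out[name] = _load_rows(fh, name, None)
    return out


def lookup_term(dictionary: Dictionary, term: str) -> DictionaryEntry | None:
    """Return the entry whose term matches under case-folding, else None."""
    if not term or not term.strip():
        raise UsageError("term must be non-empty")
    wanted = normalize_term(term)
    for entry in dictionary:
        if normalize_term(entry.term) == wanted:
            return entry
    return None


def resolve_link(
    entry: DictionaryEntry, link_name: str, dictionaries: DictionarySet
) -> DictionaryEntry:
    """Follow a declared link of an entry to the entry it points at."""
    if link_name not in entry.links:
        raise UsageError(
            f"entry {entry.id!r} declares no link named {link_name!r}"
        )
    ref = entry.links[link_name]
    target = dictionaries.get(ref.target_dictionary)
    if target is None:
        raise ReferentialIntegrityError(
            f"link {link_name!r} of entry {entry.id!r} targets unknown "
            f"dictionary {ref.target_dictionary!r}"
        )
    resolved = target.get(ref.target_id)
    if resolved is None:
        raise ReferentialIntegrityError(
            f"link {link_name!r} of entry {entry.id!r}: id {ref.target_id!r} "
            f"is absent from dictionary {ref.target_dictionary!r}"
        )
    return resolved


def validate_dictionary_set(dictionaries: DictionarySet) -> list[str]:
    """Check every declared link of every entry; return violation messages."""
    violations: list[str] = []
    for dictionary in dictionaries.values():
        for entry in dictionary:
            for link_name in entry.links:
                try:
                    resolve_link(entry, link_name, dictionaries)
                except ReferentialIntegrityError as exc:
                    violations.append(f"{dictionary.name}: {exc}")
    return violations


# ---------------------------------------------------------------------------
# term index


def _tokenize(text: str) -> list[str]:
    return [tok for tok in re.split(r"[^0-9a-z]+", normalize_term(text)) if tok]


@dataclass
class TermIndex:
    """Inverted index over a dictionary set.

    ``postings`` maps each token to the entries whose term contains it;
    full normalized terms are kept sorted so prefix queries run on ordered
    data.  Rebuilding from the same CSV set is deterministic.
    """

    postings: dict[str, list[tuple[str, str]]]
    terms: list[tuple[str, str, str]]  # (normalized term, dictionary, id)
    source: str
    _dictionaries: DictionarySet

    def entry(self, key: tuple[str, str]) -> DictionaryEntry:
        dict_name, entry_id = key
        return self._dictionaries[dict_name].entries[entry_id]


def build_term_index(dictionaries: DictionarySet, source: str = "packaged") -> TermIndex:
    postings: dict[str, list[tuple[str, str]]] = {}
    terms: list[tuple[str, str, str]] = []
    for dict_name in sorted(dictionaries):
        for entry in dictionaries[dict_name]:
            key = (dict_name, entry.id)
            terms.append((normalize_term(entry.term), dict_name, entry.id))
            for token in set(_tokenize(entry.term)):
                postings.setdefault(token, []).append(key)
    terms.sort()
    return TermIndex(postings=postings, terms=terms, source=source,
                     _dictionaries=dictionaries)


def matches_query(term: str, query: str) -> tuple[int, bool]:
    """Match predicate shared by the index and any linear-scan oracle.

    Returns (rank, matched): rank 0 for an exact full-term match, 1 for a
    raw-term prefix match, 2 when every query token is a prefix of some
    term token.
    """
    nterm, nquery = normalize_term(term), normalize_term(query)
    if nterm == nquery:
        return 0, True
    if nterm.startswith(nquery):
        return 1, True
    term_tokens = _tokenize(term)
    query_tokens = _tokenize(query)
    if query_tokens and all(
        any(tt.startswith(qt) for tt in term_tokens) for qt in query_tokens
    ):
        return 2, True
    return 3, False


def search_terms(index: TermIndex, query: str, max_n: int = 10) -> list[DictionaryEntry]:
    """Ranked prefix/token search over the index.

    An exact full-term match always ranks first; raw-term prefix matches
    come next, then token-boundary matches; ties break by term order.
    """
    if not query or not query.strip():
        raise UsageError("query must be non-empty")
    if max_n < 1:
        raise UsageError("max_n must be >= 1")
    nquery = normalize_term(query)
    query_tokens = _tokenize(query)

    # candidate set from the inverted index: any entry sharing a token
    # prefix with the first query token, plus raw-prefix candidates.
    candidates: set[tuple[str, str]] = set()
    if query_tokens:
        first = query_tokens[0]
        for token, keys in index.postings.items():
            if token.startswith(first):
                candidates.update(keys)
    for nterm, dict_name, entry_id in index.terms:
        if nterm.startswith(nquery) or nterm == nquery:
            candidates.add((dict_name, entry_id))

    ranked: list[tuple[int, str, str, str]] = []
    for key in candidates:
        entry = index.entry(key)
        rank, ok = matches_query(entry.term, query)
        if ok:
            ranked.append((rank, normalize_term(entry.term), key[0], key[1]))
    ranked.sort()
    return [index.entry((d, i)) for _, _, d, i in ranked[:max_n]]


# ---------------------------------------------------------------------------
# method classification


@dataclass
class MethodClassification:
    """A method name as found in an input file, with optional dictionary
    links to its class (level of theory) and family (ab initio,
    semi-empirical, empirical).  The specific name is always retained even
    when no dictionary entry matches, so unmapped data remains publishable.
    """

    specific_name: str
    method: DictionaryEntry | None = None
    method_class: DictionaryEntry | None = None
    method_family: DictionaryEntry | None = None


def classify_method(name: str, dictionaries: DictionarySet) -> MethodClassification:
    """Infer class and family for a method name (e.g. MP2 -> Møller-Plesset,
    ab initio) through the packaged method dictionaries."""
    if not name or not name.strip():
        raise UsageError("method name must be non-empty")
    result = MethodClassification(specific_name=name)
    qm = dictionaries.get("qm_method")
    if qm is not None:
        entry = lookup_term(qm, name)
        if entry is not None:
            result.method = entry
            if "CLASS_ID" in entry.links:
                cls = resolve_link(entry, "CLASS_ID", dictionaries)
                result.method_class = cls
                if "FAMILY_ID" in cls.links:
                    result.method_family = resolve_link(
                        cls, "FAMILY_ID", dictionaries
                    )
            return result
    generic = dictionaries.get("computational_method")
    if generic is not None:
        entry = lookup_term(generic, name)
        if entry is not None:
            result.method = entry
    return result
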