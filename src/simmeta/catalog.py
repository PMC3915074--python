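"""The survey-derived catalogue of common data elements (CDEs).

The catalogue distinguishes data *elements* (concepts such as Force
field, Thermostat, Molecule) from their *attributes* (properties such as
name, count, time constant).  Each attribute carries three legend flags
— recommended (R), derived (D), unit-bearing (U) — and an optional mean
importance score on a 1–5 Likert scale.  An attribute is recommended
when its mean score over non-N/A responses is strictly greater than 4.0
("Important"); an element is recommended when at least one of its
attributes is.

The packaged transcription ships as a delimited file with one row per
attribute (columns CATEGORY, ELEMENT, ATTRIBUTE, RECOMMENDED, DERIVED,
HAS_UNIT, MEAN_SCORE) and carries 32 elements with 72 attributes, 30 of
them recommended, across seven categories.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import SchemaError, UsageError

RECOMMENDATION_THRESHOLD = 4.0

_COLUMNS = ("CATEGORY", "ELEMENT", "ATTRIBUTE", "RECOMMENDED", "DERIVED",
            "HAS_UNIT", "MEAN_SCORE")


@dataclass(frozen=True)
class CDEAttribute:
    name: str
    element: str
    recommended: bool
    derived: bool = False
    has_unit: bool = False
    mean_score: float | None = None

    @property
    def qualified_name(self) -> str:
        return f"{self.element}/{self.name}"


@dataclass
class CDEElement:
    name: str
    category: str
    attributes: list[CDEAttribute] = field(default_factory=list)

    @property
    def recommended(self) -> bool:
        """An element is recommended if any of its attributes is."""
        return any(a.recommended for a in self.attributes)


@dataclass
class CDECatalog:
    elements: list[CDEElement]

    @property
    def categories(self) -> dict[str, list[CDEElement]]:
        out: dict[str, list[CDEElement]] = {}
        for element in self.elements:
            out.setdefault(element.category, []).append(element)
        return out

    @property
    def attributes(self) -> list[CDEAttribute]:
        return [a for e in self.elements for a in e.attributes]

    @property
    def recommended_attributes(self) -> list[CDEAttribute]:
        return [a for a in self.attributes if a.recommended]

    def knows_attribute(self, qualified_name: str) -> bool:
        return qualified_name in {a.qualified_name for a in self.attributes}


def _parse_bool(raw: str, row: int, column: str) -> bool:
    raw = raw.strip().lower()
    if raw in ("true", "1", "yes", "r", "d", "u"):
        return True
    if raw in ("false", "0", "no", ""):
        return False
    raise SchemaError(f"row {row}: unparseable boolean {raw!r} in {column}")


def load_catalog(source=None) -> CDECatalog:
    """Load the CDE catalogue (the packaged transcription by default).

    Loading is deterministic: repeated loads are structurally equal.
    Rows with an empty element name, missing legend columns, or a
    recommended flag inconsistent with the stated mean score are schema
    errors.
    """
    if source is None:
        data = (resources.files("simmeta").joinpath("data", "cde_catalog.csv")
                .read_text(encoding="utf-8"))
    elif isinstance(source, (str, Path)) and "\n" not in str(source):
        data = Path(source).read_text(encoding="utf-8")
    else:
        data = source if isinstance(source, str) else source.read()
    reader = csv.DictReader(io.StringIO(data))
    header = reader.fieldnames or []
    for column in _COLUMNS[:-1]:  # MEAN_SCORE is optional
        if column not in header:
            raise SchemaError(f"catalogue is missing column {column!r}")

    elements: dict[tuple[str, str], CDEElement] = {}
    for number, row in enumerate(reader, start=2):
        element_name = (row.get("ELEMENT") or "").strip()
        attribute_name = (row.get("ATTRIBUTE") or "").strip()
        category = (row.get("CATEGORY") or "").strip()
        if not element_name:
            raise SchemaError(
                f"row {number}: attribute {attribute_name!r} belongs to no "
                "element"
            )
        if not attribute_name:
            raise SchemaError(f"row {number}: element {element_name!r} has a "
                              "row with no attribute")
        recommended = _parse_bool(row.get("RECOMMENDED", ""), number,
                                  "RECOMMENDED")
        score_raw = (row.get("MEAN_SCORE") or "").strip()
        mean_score = float(score_raw) if score_raw else None
        if mean_score is not None:
            if (mean_score > RECOMMENDATION_THRESHOLD) != recommended:
                raise SchemaError(
                    f"row {number}: RECOMMENDED flag contradicts mean score "
                    f"{mean_score} under the strict >{RECOMMENDATION_THRESHOLD} rule"
                )
        attribute = CDEAttribute(
            name=attribute_name,
            element=element_name,
            recommended=recommended,
            derived=_parse_bool(row.get("DERIVED", ""), number, "DERIVED"),
            has_unit=_parse_bool(row.get("HAS_UNIT", ""), number, "HAS_UNIT"),
            mean_score=mean_score,
        )
        key = (category, element_name)
        if key not in elements:
            elements[key] = CDEElement(name=element_name, category=category)
        elements[key].attributes.append(attribute)

    catalog = CDECatalog(elements=list(elements.values()))
    for category, members in catalog.categories.items():
        names = [e.name for e in members]
        if len(names) != len(set(names)):
            raise SchemaError(
                f"duplicate element names within category {category!r}"
            )
    return catalog


def classify_importance(scores) -> str:
    """Apply the recommendation rule to a list of Likert responses.

    Responses are integers on the 1–5 scale or "N/A"/None; N/A responses
    are excluded from the mean.  The mean is compared strictly against
    4.0: above it the attribute is "recommended", at or below it is
    "optional".
    """
    numeric = []
    for score in scores:
        if score is None:
            continue
        if isinstance(score, str):
            if score.strip().upper() in ("N/A", "NA", ""):
                continue
            score = float(score)
        numeric.append(float(score))
    if not numeric:
        raise UsageError("importance is undefined: all responses are N/A")
    if any(not 1 <= s <= 5 for s in numeric):
        raise UsageError("Likert responses must lie on the 1-5 scale")
    mean = sum(numeric) / len(numeric)
    return "recommended" if mean > RECOMMENDATION_THRESHOLD else "optional"


@dataclass
class CompletenessReport:
    """How completely an annotation set covers the recommended attributes."""

    completeness: float
    present_recommended: list[str]
    missing_recommended: list[str]
    unknown_attributes: list[str]  # user/lab-specific extensions, not errors


def validate_annotations(triplets, catalog: CDECatalog) -> CompletenessReport:
    """Score a triplet set against the catalogue's recommended attributes."""
    present = {t.attribute for t in triplets}
    recommended = sorted({a.qualified_name
                          for a in catalog.recommended_attributes})
    known = {a.qualified_name for a in catalog.attributes}
    present_recommended = [n for n in recommended if n in present]
    missing = [n for n in recommended if n not in present]
    unknown = sorted(p for p in present if p not in known)
    completeness = (len(present_recommended) / len(recommended)
                    if recommended else 1.0)
    return CompletenessReport(
        completeness=completeness,
        present_recommended=present_recommended,
        missing_recommended=missing,
        unknown_attributes=unknown,
    )
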