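"""Render an experiment document as a collapsible HTML tree view.

Every model entity in the XML document becomes one collapsible node
(native ``<details>``/``<summary>`` markup, no scripting), so the node
count of the page equals the entity count of the model and nothing is
lost in presentation.
"""

from __future__ import annotations

from lxml import etree

from ..model import Experiment
from .xml import to_xml

#: XML tags that represent model entities (one tree node each).  Child
#: elements with other tags (quantities, dependsOn, chain, calculation)
#: render as detail lines of their parent node.
ENTITY_TAGS = frozenset({
    "experiment", "author", "grant", "system", "molecule",
    "processGroup", "process", "task", "mdParameterSet", "qmParameterSet",
    "qmmmParameterSet", "barostat", "thermostat", "forceField", "constraint",
    "restraint", "fileCollection", "file", "extendedAttribute",
})

_STYLE = """
body { font-family: sans-serif; font-size: 14px; }
details { margin-left: 1.2em; border-left: 1px dotted #999; padding-left: .5em; }
summary { cursor: pointer; }
summary .kind { color: #246; font-weight: bold; }
.attr { color: #444; margin-left: 2.6em; }
"""


def _summary_text(element) -> str:
    for key in ("name", "methodName", "attribute", "uid", "term", "id",
                "agency", "algorithm", "property"):
        value = element.get(key)
        if value:
            return value
    return element.tag


def _node(parent_div, element):
    details = etree.SubElement(parent_div, "details")
    details.set("open", "open")
    details.set("data-kind", element.tag)
    summary = etree.SubElement(details, "summary")
    kind = etree.SubElement(summary, "span")
    kind.set("class", "kind")
    kind.text = element.tag
    kind.tail = " " + _summary_text(element)
    attrs = ", ".join(f"{k}={v}" for k, v in sorted(element.attrib.items()))
    if attrs:
        line = etree.SubElement(details, "div")
        line.set("class", "attr")
        line.text = attrs
    for child in element:
        if child.tag in ENTITY_TAGS:
            _node(details, child)
        else:
            line = etree.SubElement(details, "div")
            line.set("class", "attr")
            detail = ", ".join(f"{k}={v}" for k, v in
                               sorted(child.attrib.items()))
            text = (child.text or "").strip()
            line.text = f"{child.tag}: {text or detail}"
    return details


def render_html(document) -> str:
    """Return a standalone well-formed HTML page for an experiment or its
    XML document."""
    if isinstance(document, Experiment):
        document = to_xml(document)
    if isinstance(document, (str, bytes)):
        root = etree.fromstring(
            document.encode() if isinstance(document, str) else document)
    elif hasattr(document, "getroot"):
        root = document.getroot()
    else:
        root = document

    html = etree.Element("html")
    head = etree.SubElement(html, "head")
    etree.SubElement(head, "meta", charset="utf-8")
    title = etree.SubElement(head, "title")
    title.text = root.get("name") or "experiment"
    style = etree.SubElement(head, "style")
    style.text = _STYLE
    body = etree.SubElement(html, "body")
    _node(body, root)
    return "<!DOCTYPE html>\n" + etree.tostring(
        html, pretty_print=True, encoding="unicode")


def count_entity_nodes(document) -> int:
    """Number of model-entity elements in a document (equals the number of
    collapsible nodes the HTML page shows)."""
    if isinstance(document, Experiment):
        document = to_xml(document)
    root = document.getroot() if hasattr(document, "getroot") else document
    return sum(1 for el in root.iter() if el.tag in ENTITY_TAGS)
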