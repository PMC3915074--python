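"""Look up and search controlled-vocabulary terms.

Builds the packaged term index, runs a prefix search capped at two
matches, resolves a term exactly, and classifies QM method names into
their level-of-theory class and family.
"""

from simmeta import (
    build_term_index,
    classify_method,
    load_packaged_dictionaries,
    lookup_term,
    search_terms,
)

dictionaries = load_packaged_dictionaries()
index = build_term_index(dictionaries)

print("prefix search 'AMBER FF' (max 2 matches):")
for entry in search_terms(index, "AMBER FF", max_n=2):
    print(f"  {entry.id}: {entry.term} — {entry.description}")

entry = lookup_term(dictionaries["computational_method"], "qm/mm")
print(f"\nexact lookup 'qm/mm' (case-insensitive): {entry.term}")
print(f"  {entry.description}")

print("\nmethod classification (name -> class -> family):")
for name in ("MP2", "B3LYP", "AM1", "XYZ999"):
    c = classify_method(name, dictionaries)
    klass = c.method_class.term if c.method_class else "—"
    family = c.method_family.term if c.method_family else "—"
    print(f"  {name:8s} class={klass:35s} family={family}")
# An unmapped name (XYZ999) keeps only its specific name: data with no
# dictionary match must still be publishable.
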