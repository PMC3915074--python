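"""Flatten an experiment into attribute-value-unit triplets and query it.

Flattening emits one triplet per mapped field plus derived triplets
computed through the dictionaries (force-field type, QM method class
and family).  Queries are attribute-value conjunctions over the store.
"""

import tempfile
from pathlib import Path

from simmeta import (
    assemble_directory,
    flatten_to_triplets,
    generate_md_study,
    load_packaged_dictionaries,
    query_index,
    tag_subject,
)
from simmeta.index import TripletStore

root = Path(tempfile.mkdtemp()) / "study"
generate_md_study(root, seed=1)
experiment = assemble_directory(root)
dictionaries = load_packaged_dictionaries()

triplets = flatten_to_triplets(experiment, dictionaries)
print(f"{len(triplets)} triplets; derived ones inferred via dictionaries:")
for t in triplets:
    if t.derived:
        print(f"  {t.subject}: {t.attribute} = {t.value}")

store = TripletStore(triplets=triplets)
hits = query_index(store, [("Force field/name", "=", "AMBER FF99SB"),
                           ("Ensemble/ensemble type", "=", "NPT")])
print(f"\ntasks using AMBER FF99SB in the NPT ensemble: {hits}")

tag_subject(store, hits[0], "convergence note", "plateau after 40 ns")
hits = query_index(store, [("convergence note", "contains", "plateau")])
print(f"user-tagged subjects found by substring query: {hits}")
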