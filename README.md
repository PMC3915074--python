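# simmeta

A toolkit for indexing and sharing **biomolecular simulation
metadata**. Molecular dynamics (MD), quantum chemistry (QM) and
hybrid QM/MM studies leave behind directory trees of topologies,
logs and trajectory segments with no shared description; simmeta
gives labs and repository builders a common logical model, a set of
controlled-vocabulary dictionaries, and the plumbing to turn raw
file sets into something searchable and presentable.

It is aimed at people building simulation data repositories and at
computational chemists who want their studies annotated well enough
to be found again.

## What it does

* **Model.** A *virtual experiment* is a tree: process groups (one
  per molecular system and simulated copy) → processes (runs of
  similar tasks, e.g. minimization / heating / production) → tasks
  (single computational runs), with reusable MD / QM / QM/MM
  *parameter sets*, acyclic dependencies at every level, and
  attribute–value–unit *extended attributes* for anything the model
  does not name. Molecular systems store occurrence counts (water is
  H×2 + O×1 plus a molecule count), and residue chains normalize to
  one-letter codes for sequence queries.
* **Dictionaries.** 21 CSV vocabularies — force fields and their
  types, QM methods with a class/family hierarchy (MP2 →
  Møller-Plesset → ab initio), basis sets, thermostats, barostats,
  ensembles, constraint algorithms, electrostatics models,
  enhanced-sampling and analysis methods, residues, elements,
  software, file formats — with cross-dictionary links, an inverted
  term index with ranked prefix search, and referential-integrity
  validation.
* **Parsers.** Documented plain-text dialects for topology
  (`SIMTOP`), MD output (`MDLOG`) and QM output (`QMLOG`) files plus
  content-based format detection; executable build strings such as
  `EM64L-G09RevC.01` split into product / revision / architecture.
* **Assembly.** Natural ordering of task files (`2.traj` before
  `10.traj`), grouping of parsed records into a valid experiment
  tree, and both legal groupings of replica-exchange runs.
* **Indexing.** Experiments flatten into AVU triplets, including
  *derived* triplets inferred through the dictionaries (force-field
  type, method class/family); conjunctive attribute-value queries
  are guaranteed equivalent to a linear scan.
* **CDE catalogue.** The packaged common-data-element catalogue (32
  elements, 72 attributes, 30 recommended under the strict
  mean-score > 4.0 rule) scores annotation completeness of any
  triplet set.
* **Serialization.** XML documents with a published XSD and
  round-trip identity, collapsible HTML tree views, and relational
  DDL (with per-entity extended-attribute tables) that executes on
  sqlite3 and loads every dictionary row with foreign keys enforced.
* **Analysis descriptors.** Dimensions/variables descriptions of
  derived datasets (0-D scalar, 1-D series, 2-D matrix), provenance
  records, JSON sidecars, and a currency check that flags an
  analysis as needing an update when its trajectory is newer.
* **Fixtures.** Seeded generators for MD, REMD and QM study
  directories with ground-truth manifests, byte-identical under
  regeneration.

## A worked example

```python
import tempfile
from pathlib import Path
from simmeta import (assemble_directory, flatten_to_triplets,
                     generate_md_study, load_packaged_dictionaries,
                     query_index)
from simmeta.index import TripletStore

root = Path(tempfile.mkdtemp()) / "md-study"
generate_md_study(root, seed=1)                 # fixture study of RNA
experiment = assemble_directory(root)           # parse + assemble
for group in experiment.process_groups:
    for process in group.processes:
        task = process.tasks[0]
        print(process.tasks[0].description, task.md_parameters.n_steps)

store = TripletStore(triplets=flatten_to_triplets(
    experiment, load_packaged_dictionaries()))
print(query_index(store, [("Force field/name", "=", "AMBER FF99SB"),
                          ("Ensemble/ensemble type", "=", "NPT")]))
```

prints

```
minimization 938
heating 11462
production 213560
['task:task-b5d1efe1f0']
```

— the three stages became three processes in one process group, with
the step counts parsed from the MD logs, and the query found the one
task that simulates with AMBER FF99SB in the NPT ensemble. The
flattened store also carries derived triplets the raw files never
state, e.g. `Force field/force field type = classical`, inferred
through the force-field dictionary.

The `examples/` directory has one short script per capability
(dictionary search, parse/assemble, indexing, XML/HTML/DDL, CDE
completeness, analysis descriptors). A thin CLI wraps the same
library surface:

```sh
simmeta dict lookup force_field "AMBER FF" -n 2
simmeta fixtures md /tmp/study --seed 1
simmeta summarize /tmp/study --html > study.html
simmeta catalog stats
simmeta schema export
```

## Layout

```
src/simmeta/            model, dictionaries, parsers, assembly,
                        index, catalog, analysis, fixtures, cli
src/simmeta/serializers xml / html / ddl
src/simmeta/data/       dictionary CSVs, CDE catalogue, XSD
docs/methods.md         the model, rules and numerical choices
docs/fixture-dialects.md  the SIMTOP / MDLOG / QMLOG grammars
examples/               one narrative script per capability
tests/                  pytest suite (unit + property + end-to-end)
```
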