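# Methods

## The problem

Biomolecular simulation studies — classical molecular dynamics (MD),
quantum chemistry (QM), and hybrid QM/MM — produce sprawling directory
trees of input files, logs and trajectory segments with no shared
metadata scheme. simmeta implements a logical model and a set of
controlled vocabularies for indexing such studies: enough structure to
find, compare and present experiments, deliberately not enough to
re-execute them (raw files remain the ground truth).

## The experiment model

A *virtual experiment* decomposes into three levels:

* **process group** — all computation targeting one molecular system;
  each simulated copy of a system is its own group, and separately
  studied subsystems (ligand vs. receptor) get separate groups;
* **process** — a run of *similar* tasks. Similarity is keyed on the
  run context, so a minimization → heating → production series is one
  group with three processes even though heating and production are
  both MD;
* **task** — a single computational run defined by one input file,
  carrying method-agnostic attributes (boundary conditions, solvent
  type, simulated conditions, software, computing environment,
  execution record) and method-specific *parameter sets*.

Parameter sets are reusable bundles: an MD set (force fields, thermo-
and barostat, ensemble, constraints/restraints, electrostatics model,
step count/length, and a collision frequency that is only meaningful
for stochastic dynamics), a QM set (method, basis set, frozen-core /
pseudopotential flags, plane-wave cutoff, convergence), and a QM/MM
set (boundary treatment). A QM/MM task references all three, which is
how hybrid methods compose without new task types. Multi-level (ONIOM
-style) tasks would need a task type referencing several QM sets; they
are sketched in the model's lineage but not implemented here.

Dependencies are recorded between entities of the same kind only
(task→task, process→process, group→group) and must stay acyclic;
`validate_experiment` reports containment violations (an entity in two
parents), cycles, missing parameter sets, negative reference
conditions, inconsistent execution timestamps, and topology files
attached to tasks (they belong to the molecular system). Violations
are data, not exceptions, so callers can triage.

Molecular systems store *occurrence counts*, not instances: water is
H×2 + O×1 plus a molecule count. Residue chains are kept twice — the
*specific chain* as named in the topology, and a *normalized chain* in
one-letter codes derived through the residue dictionary (unknown
residues become `X`), which enables software-independent sequence
queries.

### Design choices where the design was open

* Entity identifiers are derived deterministically from content +
  position (SHA-1 prefix) because parsers rarely find explicit ids and
  reproducible fixtures need stable ones.
* Extended attributes (attribute–value–unit triplets with an optional
  concept id, attachable to any entity) are multi-valued; attaching
  the same attribute twice keeps both triplets.
* Units are opaque strings, copied verbatim, never converted.
* Derived properties (force-field type, QM method class/family, basis
  set type, normalized chain) are *not* stored on entities; they are
  materialized at flattening time through the dictionaries, keeping
  stored and inferable data distinct.
* Simulated copies are identified by an explicit manifest/file key
  (`COPY`), never by content hashing.
* Replica groupings: a replica-exchange run defaults to one process
  holding all replica tasks; `per_replica` splits it, since both
  readings of "similar tasks" are defensible. Tasks inside one run are
  left unchained (replicas execute in parallel); dependencies chain
  across run boundaries.

## Dictionaries

Twenty-one controlled vocabularies ship as CSV files (`ID`, `TERM`,
`DESCRIPTION`, plus scalar extras such as citations or boolean flags,
and `<TARGET>_ID` link columns acting as foreign keys). The QM method
hierarchy is three-tiered: a specific method (MP2, B3LYP, AM1) links
to its class (Møller-Plesset, DFT, ...) which links to its family
(ab initio / semi-empirical / empirical); a method name alone
therefore suffices to infer the level of theory. A method may arguably
belong to several classes (multi-reference CI, hybrids); the schema
keeps a single class link per method for relational simplicity.
Force-field entries carry a type link (classical / polarizable /
reactive) and a coarse-grain flag. Basis sets carry their type
(atomic / plane-wave) as a scalar column.

Matching is case-insensitive and whitespace-normalized. The term index
is a hand-rolled inverted index (token postings plus a sorted term
list); search ranks exact full-term matches first, then raw-term
prefix matches, then token-boundary matches, with ties broken by term
order — the ranking rule is this package's choice, as is the exact
match predicate (every query token must prefix some term token).
Synonyms are not implemented; the CSV design reserves room for a
per-dictionary synonym file. Dictionary entries beyond the handful of
terms fixed by the model's worked examples are provisional
transcriptions and expected to grow.

## The CDE catalogue and the recommendation rule

The catalogue distinguishes data *elements* (concepts) from
*attributes* (properties) and ships as one CSV row per attribute with
legend flags: recommended (R), derived (D), unit-bearing (U), plus an
optional mean importance score on a 1–5 Likert scale. The packaged
transcription holds 32 elements and 72 attributes (30 recommended)
across seven categories — authorship, platform, molecular system,
molecules, methods, molecular dynamics, quantum mechanics. (The
survey that produced the list described "6 categories" but enumerated
these seven; the transcription keeps seven and documents rather than
resolves the discrepancy.) Per-attribute scores are not all published;
`MEAN_SCORE` is therefore optional in the schema, and rows that do
carry one are checked at load time against the flag.

The recommendation rule: an attribute is recommended iff its mean
score over non-N/A responses is strictly greater than 4.0
("Important"). N/A responses are excluded from the mean — the Likert
scale makes "not applicable" a non-response, though the source rule
left this unstated. An element is recommended iff at least one of its
attributes is. `classify_importance` is permutation-invariant and
monotone (raising one score never demotes an attribute), and
annotation completeness = fraction of recommended attributes present
is bounded in [0,1] and monotone under triplet addition.

## Flattening and the triplet index

`flatten_to_triplets` walks a validated experiment and emits one
attribute–value–unit triplet per populated mapped field. Attribute
names are qualified as `<Element>/<attribute>` (e.g.
`Force field/name`, `Simulated conditions/reference temperature`),
keyed to the CDE catalogue so completeness scoring is a set
intersection; the field→attribute map is version-tagged in
`simmeta/index.py`. Derived triplets are materialized at flattening
time (not computed at query time) so stores are self-contained.
Subjects are `kind:id` strings (experiment, system, task, file).
Queries support equality and case-insensitive substring containment
over conjunctions of predicates, and are by construction equivalent
to a linear scan — the scan *is* the implementation, and the test
suite holds an independent oracle to that contract. User tags are
accepted for any attribute; catalogue-known names are flagged
standard, others lab-specific.

## Serialization

**XML.** The document mirrors the tree: experiment → systems →
process groups → processes → tasks → parameter sets/files. The
element vocabulary is authored here and published as
`simmeta/data/experiment.xsd`; `from_xml` validates against it before
reconstruction, so unknown elements are rejected with their path.
Dependencies serialize as id references (never nesting) to keep the
document a tree; systems shared by several groups are written once
and referenced. Round-tripping is the identity on the model,
including extended attributes and dependencies. Floats are written in
shortest-repr form so numeric fields survive the trip exactly.

**HTML.** The tree view is built as an element tree from the XML
(template-transformation in shape, without an XSLT engine): one
native `<details>/<summary>` node per model entity, scalar children
rendered as detail lines. Node count equals model entity count.

**DDL.** `generate_ddl` emits one table per entity and per dictionary,
foreign keys for all links, and a companion
`<table>_extended_attribute` table per extended-attribute-bearing
entity (the relationally sound alternative to one global triplet
table). Tables are created in dependency order and dropped first, so
the script is idempotent. The baseline dialect is portable SQL that
sqlite3 executes as-is; the dialect name is a generation flag.
`load_dictionaries_into` inserts every packaged row with
`PRAGMA foreign_keys = ON`, making referential integrity an
executable check.

## Analysis descriptors

Derived data is described by named dimensions and variables (rank =
number of dimension references; 0 = scalar, 1 = series, 2 = matrix),
a provenance record (method name/description, program name+version,
command, timestamp, optional reference system), and optional filters.
Descriptors persist as JSON sidecars (`<artifact>.meta.json`) —
delimited files dominate analysis practice, so the self-describing
structure lives beside the data rather than inside it. Space filters
stay as opaque selection strings with a program tag; translating
every program's atom-selection syntax into a common form is out of
scope, and filters are never inferred from the command. Currency
checking compares whole-second modification times, ties counting as
current; a known-newer dependency wins over an unknown one (the
answer is known regardless), otherwise any missing timestamp yields
"unknown". No analysis is ever computed here — description only.

## The fixture generators

The generators define the study conditions everything is tested
under. `generate_md_study` emulates an MD study of RNA: a solvated
duplex (12-residue chain drawn from A/U/G/C, ~800–1200 explicit
waters with the H×2/O×1 occurrence signature, AMBER-FF99SB + TIP3P
force-field pair), minimization (a few hundred steps), heating (NVT,
2 fs steps, 300 K), and production (NPT, PME, SHAKE on
hydrogen-involving bonds, 1 bar / 300 K, 2 fs steps, 10⁵-range step
counts), run under AMBER 12 via SANDER or PMEMD on Linux/x86_64
hosts. Production writes twelve placeholder trajectory segments so
the set always contains a pair ("2.traj"/"10.traj") that naive string
sorting mis-orders. `generate_remd_study` writes one production MD
output per temperature replica (300 K + 10 K ladder, generalized
ensemble); `generate_qm_study` writes one input/output pair (MP2 /
6-31G* by default, Gaussian 09 with an `EM64L-G09RevC.01`-style build
string) plus a small-molecule topology.

Every value flows from one seeded generator; timestamps are
config-supplied, never wall-clock, so regeneration at equal (seed,
config) is byte-identical, and each manifest carries the exact model
objects the tree must parse back to — the recovery tests compare
field-for-field, with the manifest built from the config, not from
the parsers.

What the fixtures deliberately are **not**: real AMBER/Gaussian
grammars. The dialects (see `fixture-dialects.md`) carry the same
information with a trivial grammar, so passing tests demonstrate the
model, assembly, indexing and serialization logic — not robustness to
the quirks of real engine output. Trajectory payloads are named,
sized placeholders; binary formats (NetCDF, DCD) are treated as
opaque files with format tags throughout.

## Problem sizes and numerics

The test suite and the acceptance script size their ensembles to what
the properties need: 1,000 random filename sets for the ordering
oracle, 1,000 random triplet stores for query/scan equivalence, the
exhaustive 1,554 response lists of length ≤ 4 for the recommendation
rule, a 52-study matrix (MD configs × REMD 1–8 replicas × QM configs)
for round-trip identity and a 22-cell matrix for generator↔parser
recovery. All are exact structural checks — agreement is expected at
100%, not within a tolerance — and the full suite runs in seconds.

## Known limitations

* Dictionary content beyond the terms the model's examples fix is
  provisional; coverage, not curation, is the claim.
* One class link per QM method; multi-class methods lose secondary
  classifications.
* Trajectory segments attach to the last MD task of a group; when
  several groups share one segment pool the attachment is ambiguous
  and simply repeated.
* File-name ordering with no digits at all falls back to plain
  lexicographic order and is flagged on the experiment as an extended
  attribute rather than guessed.
* No persistence layer, no object-relational runtime, no remote
  dictionary service, no synonym/ontology mapping, no unit
  conversion.
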