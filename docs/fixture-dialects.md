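# Fixture file dialects

Three line-oriented plain-text dialects stand in for engine-specific
simulation formats. They carry the same metadata a topology file, an
MD output log and a QM output log would, with a grammar simple enough
to be bit-exact in tests. All files are UTF-8; blank lines and lines
starting with `#` are ignored.

## SIMTOP — topology

```
%SIMTOP 1.0
%SECTION SYSTEM
NAME = RNA duplex in explicit water
MOLECULE_TYPES = 2
%SECTION MOLECULE
NAME = RNA
COUNT = 1
TYPE = RNA
N_RESIDUES = 3
RESIDUES = A,U,G
ATOMS = C:27,N:12,O:18,H:33,P:3
%SECTION MOLECULE
NAME = WAT
COUNT = 1021
TYPE = solvent
N_RESIDUES = 1
RESIDUES = WAT
ATOMS = H:2,O:1
```

* First line must be the `%SIMTOP` magic.
* One `SYSTEM` section; one `MOLECULE` section per molecule type.
* `RESIDUES` is the specific chain in file order; `ATOMS` lists
  per-molecule atom occurrence counts as `ELEMENT:count`.
* Declared counts are checked: `MOLECULE_TYPES` against the number of
  molecule sections, `N_RESIDUES` against the listed chain; a mismatch
  is a parse error.

## MDLOG — minimization / MD output

```
%MDLOG 1.0
SYSTEM = RNA duplex in explicit water
TASK_KIND = md                    # minimization | md  (required)
RUN_CONTEXT = production          # minimization | heating | equilibration | production
SOFTWARE = AMBER
VERSION = 12
EXECUTABLE = PMEMD
OS = Linux
CPU_ARCH = x86_64
MACHINE_NAME = kingspeak.chpc.utah.edu
BOUNDARY_CONDITIONS = periodic
SOLVENT_TYPE = explicit
FORCE_FIELDS = AMBER FF99SB;TIP3P
CALCULATION = Dynamics
N_STEPS = 250000
STEP_LENGTH_PS = 0.002
THERMOSTAT = Langevin
COLLISION_FREQUENCY_PS = 2.0
ENSEMBLE = NPT
BAROSTAT = Berendsen
REF_TEMPERATURE_K = 300.0
REF_PRESSURE_BAR = 1.0
ELECTROSTATICS = PME
CONSTRAINTS = SHAKE:bonds involving hydrogen
START = 2013-05-01T10:00:00
END = 2013-05-01T12:00:00
ELAPSED_SECONDS = 7200.0
FOOTER: COMPLETE
```

* `KEY = value` lines after the `%MDLOG` magic; any other non-blank,
  non-comment line is a parse error reported with its line number.
* Units ride in the key names (`_PS`, `_K`, `_BAR`) and are attached
  to the parsed quantities verbatim.
* `FORCE_FIELDS`, `CONSTRAINTS`, `RESTRAINTS`, `CALCULATION` are
  semicolon-separated; constraints/restraints use `name:target`.
* `COPY = n` marks one of several simulated copies of the system.
* The `FOOTER: <status>` line carries the termination status; a
  missing footer parses as status `incomplete`.
* Absent keys leave the corresponding record fields unset — parsers
  never invent values.

## QMLOG — QM output

```
%QMLOG 1.0
SYSTEM = guanine
SOFTWARE = Gaussian
VERSION = 09
EXECUTABLE = EM64L-G09RevC.01
BOUNDARY_CONDITIONS = non-periodic
SOLVENT_TYPE = vacuum
CALCULATION = Geometry optimization
METHOD = MP2
BASIS_SET = 6-31G*
FROZEN_CORE = true
PSEUDOPOTENTIALS = false
PLANE_WAVE_CUTOFF_EV = 400.0
CONVERGED = true
START = 2013-06-10T08:00:00
END = 2013-06-10T08:30:00
ELAPSED_SECONDS = 1800.0
FOOTER: COMPLETE
```

Same grammar as MDLOG with QM-specific keys. `METHOD` and
`BASIS_SET` are captured verbatim as specific names; dictionary
resolution (method class/family, basis-set type) happens later, at
flattening time, and an unmapped name is retained without a link.

## TRAJ — trajectory placeholder

```
%TRAJ segment 7
frames = 354
```

Opaque stand-in for a binary trajectory segment: correct name, size
and count only. Detected by the `%TRAJ` magic and never parsed
further.

## Detection

`detect_format` is content-based: the magic first lines above map to
the `SIMTOP` / `MDLOG` / `QMLOG` / `TRAJ` file-format terms, records
starting `ATOM`, `HETATM` or `HEADER` map to `PDB`, and anything else
(including an empty file) is `unknown`.
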