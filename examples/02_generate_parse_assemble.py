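"""Generate a fixture MD study, parse it, and assemble the experiment.

The generator writes a minimization-heating-production study of a
solvated RNA duplex; parsing the tree and assembling it yields one
process group (one system, one copy) with three processes, and the
trajectory segments attach in natural numeric order, so "2.traj"
precedes "10.traj".
"""

import tempfile
from pathlib import Path

from simmeta import assemble_directory, generate_md_study, validate_experiment

root = Path(tempfile.mkdtemp()) / "md-study"
manifest = generate_md_study(root, seed=1)
print(f"generated {manifest.system.name!r} study in {root}")
print(f"  stages: {[r.run_context for r in manifest.records]}")

experiment = assemble_directory(root)
print(f"\nassembled experiment {experiment.id}")
for group in experiment.process_groups:
    print(f"  process group on {group.system.name!r}:")
    for process in group.processes:
        task = process.tasks[0]
        print(f"    process {task.description or task.task_kind}: "
              f"{len(process.tasks)} task(s), "
              f"{task.md_parameters.n_steps} steps")

report = validate_experiment(experiment)
print(f"\nstructural validation: "
      f"{'clean' if report.valid else report.violations}")

last_md = [t for g in experiment.process_groups for p in g.processes
           for t in p.tasks][-1]
traj = [f.uid for f in last_md.files if f.format == "TRAJ"]
print(f"trajectory segments in natural order: {traj[:4]} ... {traj[-1]}")
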