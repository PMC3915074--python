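"""Describe a derived analysis dataset and check its currency.

An RMSD time series is described by dimensions/variables, given a
provenance record (method, program, command, timestamp), persisted as
a JSON sidecar, and checked for currency against its trajectory
dependency's modification time.
"""

import tempfile
from pathlib import Path

from simmeta import (
    build_provenance,
    check_currency,
    describe_file,
    load_descriptor,
    save_descriptor,
)

root = Path(tempfile.mkdtemp())
artifact = root / "rmsd.csv"
artifact.write_text("frame,rmsd\n" + "".join(
    f"{i},{0.5 + 0.01 * i:.3f}\n" for i in range(1, 101)))

descriptor = describe_file(artifact)
print("inferred variables:")
for v in descriptor.variables:
    print(f"  {v.name}: {v.value_type}, rank {v.rank}, "
          f"dims {[descriptor.dimensions[d] for d in v.dimensions]}")

descriptor.provenance = build_provenance(
    "RMSD", "Root mean square deviation calculation",
    program=("CPPTRAJ", "13.0"),
    command="cpptraj -i rmsd.in", timestamp="2013-07-01T12:00:00",
    reference="experimental")
descriptor.file_dependencies = ["traj/1.traj"]
sidecar = save_descriptor(descriptor)
print(f"\nsidecar written to {sidecar.name}; "
      f"reload lossless: {load_descriptor(sidecar) == descriptor}")

for dep_time, label in ((900, "older trajectory"),
                        (2000, "newer trajectory")):
    status = check_currency(descriptor,
                            {str(artifact): 1000, "traj/1.traj": dep_time})
    print(f"dependency {label}: analysis is {status}")
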