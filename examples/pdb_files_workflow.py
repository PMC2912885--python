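"""File-level workflow: superpose two PDB files and write annotated output.

Writes a synthetic pair to PDB, runs the robust superposition on the files,
and exports the superposed mobile structure (stiffness scales in the B-factor
column, ready for colouring in a viewer), a per-residue scale table, and a
text summary.  With real structures, replace the paths and pass e.g.
``chain="A"`` and the domain ranges you care about.
"""

import tempfile
from pathlib import Path

import numpy as np

from corefit import RigidTransform, write_with_weights
from corefit.synthetic import generate_domain_motion
from corefit.workflows import superpose_files

workdir = Path(tempfile.mkdtemp(prefix="corefit_"))
pair, truth = generate_domain_motion(150, core_fraction=0.7, seed=4)
n_core = int(truth.core_mask.sum())
mobile = workdir / "mobile.pdb"
reference = workdir / "reference.pdb"
write_with_weights(pair.x, RigidTransform.identity(), np.ones(pair.n), mobile)
write_with_weights(pair.y, RigidTransform.identity(), np.ones(pair.n), reference)

report = superpose_files(
    mobile,
    reference,
    model="student",
    subsets={"core": f"1-{n_core}", "mobile": f"{n_core + 1}-{pair.n}"},
    out_prefix=str(workdir / "fit"),
)
print(report.summary())
print(f"\noutputs written under {workdir}:")
for p in sorted(workdir.glob("fit_*")):
    print(f"  {p.name}")
print(
    "\nThe per-range RMSDs separate the conserved core (small) from the moving\n"
    "block (large); fit_superposed.pdb carries the stiffness scales as\n"
    "B-factors, so any structure viewer can colour the invariant core."
)
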