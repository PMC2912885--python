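"""Robust vs least-squares superposition of a protein with a moving domain.

Builds a synthetic 200-residue pair in which 70% of the chain (the core)
moves rigidly with 0.3 Å jitter while the remaining block additionally swings
by ~30 degrees and 20 Å — the classic domain-motion situation.  A heavy-tailed
displacement model should lock onto the core; the Gaussian (plain RMSD) fit
gets dragged toward a compromise.
"""

import numpy as np

from corefit import MatchedPair, RigidTransform, fit_em, rmsd, rotation_angle, weighted_superpose
from corefit.synthetic import generate_domain_motion

pair, truth = generate_domain_motion(200, core_fraction=0.7, core_noise_sd=0.3, seed=1)
core_ids = pair.x.residue_ids[truth.core_mask]
core_pair = MatchedPair(pair.x.subset(truth.core_mask), pair.y.subset(truth.core_mask))
oracle = rmsd(core_pair, weighted_superpose(core_pair))
print(f"core-only oracle fit: {oracle:.3f} A RMSD over the true core\n")

for model in ("gauss", "student", "kdist"):
    fit = fit_em(pair, model)
    err = rotation_angle(
        RigidTransform(fit.transform.rotation @ truth.transform.rotation.T, np.zeros(3))
    )
    print(
        f"{model:8s} core RMSD {rmsd(pair, fit.transform, core_ids):6.3f} A   "
        f"overall RMSD {rmsd(pair, fit.transform):6.3f} A   "
        f"rotation error vs true core transform {err:5.2f} deg"
    )

print(
    "\nThe heavy-tailed fits reach the oracle's core RMSD (their overall RMSD is\n"
    "larger because the mobile block is left out of the fit, exactly as wanted);\n"
    "the Gaussian fit compromises between core and mobile block and misses the\n"
    "true core transform by several degrees."
)
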