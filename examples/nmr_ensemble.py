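"""Superposing a conformer ensemble onto its estimated mean structure.

Emulates an NMR ensemble: 10 conformers share a well-defined core (0.2 Å
jitter) while a C-terminal tail swings about a hinge.  The ensemble fit
estimates one rigid transform per conformer, a mean structure, and one
stiffness scale per residue shared across conformers; the per-domain RMS
deviation from the mean ("internal RMSD") is the precision statistic usually
quoted for NMR structures.
"""

import numpy as np

from corefit import ensemble_rmsd, fit_ensemble
from corefit.synthetic import generate_ensemble

conformers, truth = generate_ensemble(n=120, k=10, core_fraction=0.6, seed=2)
core_ids = conformers[0].residue_ids[truth.core_mask]
tail_ids = conformers[0].residue_ids[~truth.core_mask]

for model in ("gauss", "student"):
    fit = fit_ensemble(conformers, model)
    print(
        f"{model:8s} internal RMSD: core {ensemble_rmsd(fit, core_ids):5.3f} A, "
        f"tail {ensemble_rmsd(fit, tail_ids):6.3f} A, "
        f"all {ensemble_rmsd(fit):6.3f} A"
    )

fit = fit_ensemble(conformers, "student")
n_core = int(truth.core_mask.sum())
top = np.argsort(fit.scales)[::-1][:n_core]
hit = 100.0 * np.mean(truth.core_mask[top])
print(
    f"\ntop-{n_core} stiffness scales recover {hit:.0f}% of the true core.\n"
    "Under the Student t model the core superposes to ~the jitter level while\n"
    "the mobile tail is down-weighted; the Gaussian fit spreads the error over\n"
    "the whole chain and overstates the core imprecision."
)
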