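"""Posterior superposition ensembles: how well-defined is the fit?

Runs the Gibbs sampler on the domain-motion pair under the Gaussian and the
Student t model and summarises the spread of the sampled rotations.  A narrow
spread means the superposition is well determined; the Gaussian model,
unable to discount the moving block, is left uncertain about the frame.
The 25 sampled transforms per model are the usual way to visualise this —
apply each to the mobile structure and render the stack.
"""

import numpy as np

from corefit import GibbsOptions, RigidTransform, rotation_angle, run_gibbs
from corefit.synthetic import generate_domain_motion

pair, truth = generate_domain_motion(200, core_fraction=0.7, seed=1)

for model in ("gauss", "student"):
    chain = run_gibbs(pair, model, GibbsOptions(n_samples=150, burn_in=50, seed=3))
    mean_R = np.mean([T.rotation for T in chain.transforms], axis=0)
    U, _, Vt = np.linalg.svd(mean_R)
    center = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
    spread = [
        rotation_angle(RigidTransform(T.rotation @ center.T, np.zeros(3)))
        for T in chain.transforms
    ]
    err = rotation_angle(
        RigidTransform(center @ truth.transform.rotation.T, np.zeros(3))
    )
    print(
        f"{model:8s} rotation spread: mean {np.mean(spread):5.2f} deg, "
        f"95th pct {np.percentile(spread, 95):5.2f} deg; "
        f"posterior centre off truth by {err:5.2f} deg"
    )

print(
    "\nThe Student t posterior concentrates tightly on the true core transform;\n"
    "the broad Gaussian ensemble signals that a least-squares superposition of\n"
    "these structures is not well defined."
)
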