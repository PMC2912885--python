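"""Bayes-factor selection of the displacement model.

Generates a structure pair whose non-rigid displacements follow a Student t
scale mixture (alpha=1, beta=1: many small shifts, occasional large ones),
runs one Gibbs chain per candidate model, and ranks the models by their
harmonic-mean estimate of the log marginal likelihood.
"""

from corefit import GibbsOptions, compare_models
from corefit.synthetic import generate_pair

pair, truth = generate_pair(200, model="student", seed=7)
result = compare_models(pair, opts=GibbsOptions(n_samples=300, burn_in=100, seed=1))

print("log-evidence per model (higher is better):\n")
print(result.report())
print(
    f"\nbest model: {result.ranking[0]} — the generating family wins, the K\n"
    "distribution (also heavy-tailed) is close, and the Gaussian is far behind\n"
    "because it cannot accommodate the large-amplitude outliers.  Always read\n"
    "the estimates together with their standard errors: the harmonic-mean\n"
    "estimator is only trustworthy for orderings, not point values."
)
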