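# Methods

## Generative model

Two structures with matched Cα positions `x_i`, `y_i` (i = 1…N) are related by

    y_i = R x_i + t + d_i,

a proper rotation `R`, translation `t`, and non-rigid displacements `d_i`.
The displacement density `f(d)` is assumed zero-mean and isotropic (so that
superposing x onto y or y onto x gives the same answer), and is modelled as a
scale mixture of Gaussians: each position carries a latent inverse variance
`s_i ~ g(s; α, β)` and `d_i | s_i ~ N(0, s_i⁻¹ I₃)`.  The `s_i` act as
learned positional weights — minimizing the negative log-likelihood over
`(R, t)` at fixed scales is exactly a weighted RMSD fit.

Mixing densities and the resulting closed forms (all verified against direct
quadrature of the mixture integral in the test suite):

| mixing `g(s)` | displacement density `f(d)` |
|---|---|
| Gamma(α, rate β) | 3-D Student t: `Γ(α+3/2)/Γ(α) · βᵅ (2π)^{-3/2} (β+‖d‖²/2)^{-(α+3/2)}` |
| Inverse-Gamma(α, β) | 3-D K distribution: `2(2π)^{-3/2} βᵅ/Γ(α) · (2β/‖d‖²)^{(3/2-α)/2} K_{3/2-α}(√(2β)‖d‖)` |
| Inv-Gamma(2, λ²/2) | 3-D Laplace `λ³/(8π) e^{-λ‖d‖}` (the K member at α=2; derived here because the usual statement of this special case is ambiguous, and confirmed by the Bessel reduction at half-integer order) |
| point mass at τ | isotropic Gaussian with precision τ |

Conditional scale posteriors: Student → `Gamma(α + 3/2, β + ‖d‖²/2)`;
K → `GIG(3/2 − α, chi = 2β, psi = ‖d‖²)` with the convention
`GIG(p, chi, psi) ∝ s^{p−1} exp(−(chi/s + psi·s)/2)`.  The (chi, psi)
orientation follows from expanding `N(d; 0, s⁻¹)·InvGamma(s; α, β)` — the
`1/s` coefficient is `2β` — and is pinned down by a quadrature test, since
the GIG literature uses both argument orders.

## EM

Per cycle: (1) weighted Kabsch fit with weights `E[s_i]`; (2) conjugate CM
update of β; (3) root-finding CM update of α from the digamma score; (4)
E-step refresh of the scale expectations.  Two choices matter:

- The α and β updates consume the exact E-step sufficient statistics
  `E[s]`, `E[1/s]`, `E[log s]` under the current scale posteriors (Gamma:
  digamma forms; GIG: Bessel ratios, with `∂_p log K_p` by central
  difference).  Conditioning α on the point values `E[s]` instead — the
  naive reading of "update α given the scales" — underestimates scale
  dispersion, makes α drift upward without bound on heavy-tailed data, and
  breaks monotonicity.  With the exact statistics the procedure is a proper
  ECM on the marginal posterior and the tracked objective is monotone to
  numerical precision (asserted at 1e-6 relative slack per step).
- β uses the MAP maximizer `(Nα + a_β − 1)/(Σ· + b_β)` rather than the
  posterior mean (shape offset of one): the objective we monitor is the
  negative log *posterior*, and only the maximizer guarantees descent.  The
  standalone `update_beta`/`update_alpha` functions keep the posterior-mean
  and point-scale contracts for use outside the EM loop.

Objective: `−Σ log f(d_i; α, β) − log hyperprior(α, β)` with the scales
marginalised analytically.  Convergence: relative change < 1e-8 (default) or
200 iterations; typical fits converge in 30–60 iterations.  The Gaussian
model needs no iteration: unweighted Kabsch plus the precision MLE
`3N/Σ‖d‖²`.  The Laplace model runs the K machinery with α pinned at 2.

Initial scales are uniform by default (deterministic, reproducible);
`n_starts > 1` adds seeded random initialisations and keeps the best
posterior, which matters for genuinely bimodal cases (two similar domains,
either of which can serve as the core).

## Gibbs sampler

Systematic scan per sweep: scales → rotation → translation → β → α.

- **Scales**: vectorised Gamma draws (Student) or GIG draws via
  `scipy.stats.geninvgauss` (K).
- **Rotation**: the conditional is `p(R) ∝ exp(tr(AᵀR))` with
  `A = Σ s_i ỹ_i x̃_iᵀ` over weighted-centred coordinates.  In quaternion
  coordinates `tr(AᵀR(q)) = qᵀB q` (the 4×4 matrix is built numerically by
  polarisation, avoiding sign-convention errors), so the conditional is a
  Bingham distribution on S³, sampled exactly by rejection from an
  angular-central-Gaussian envelope.  The acceptance bound is valid at every
  concentration; `A = 0` yields Haar-uniform rotations.  Correctness is
  checked against importance-reweighted uniform rotations (KS test).
- **Translation**: conjugate isotropic Gaussian with precision
  `Σ s_i + 1/σ_t²`; the zero-centred prior (σ_t = 100 Å by default) keeps the
  evidence integral proper.  Because the rotation is drawn from the
  translation-marginalised conditional under a *flat* t prior and the proper
  prior only enters the t draw, the scheme is a blocked update with an
  O(1/(σ_t² Σs)) ≈ 1e-4 approximation — far below Monte-Carlo resolution, and
  invisible to the prior-recovery (successive-conditional) test in the suite.
- **β**: conjugate Gamma (Student: rate `Σ s_i + b`; K: rate `Σ 1/s_i + b`).
- **α**: the conditional is log-concave under the Gamma hyperprior (the
  digamma trigamma bound `ψ'(α) > 1/α²` gives strict concavity for N ≥ 1),
  so adaptive rejection sampling with tangent envelopes applies; if envelope
  construction fails numerically the code falls back to a few slice-sampling
  updates, which leave the same conditional invariant.

Defaults: 200 samples after 50 burn-in sweeps, thin 1 — both algorithms
reach their plateau well within 50 sweeps on all fixtures.  Chains are
exactly reproducible from `(seed, options)` and exportable as a TSV (9
rotation entries, translation, α, β, logL per row).

Joint correctness is tested Geweke-style: alternating forward data
simulation with one Gibbs parameter sweep must leave the hyperprior
invariant; the marginal mean and variance of α and β are checked against
Gamma(4, 2) at batch-mean precision for both heavy-tailed models.

## Evidence and model choice

Per model, the log marginal likelihood is estimated from the chain by the
harmonic-mean identity `log Z ≈ −log mean(exp(−log L))` computed with
log-sum-exp; `log L` is the *scale-marginalised* likelihood at the sampled
`(R, t, α, β)`.  The estimator's instability is treated as a first-class
fact: a 10-block jackknife SE accompanies every estimate, comparisons are
made on orderings and intervals only, and the conjugate-Gaussian unit test
deliberately uses a prior no broader than the likelihood — the regime where
the estimator is reliable.  One caveat a user should know: on
Gaussian-generated data the Student and K models (which nest the Gaussian as
their α→∞ limit) score indistinguishably from it, but the Laplace model does
not nest the Gaussian (its shape is fixed) and honestly scores a few nats
lower; claims that all heavy-tailed models tie on rigid data overstate the
nesting argument.

## Ensemble superposition

K conformers are fitted to a latent mean structure with one transform per
conformer and one shared scale per position.  The scale posterior pools
residuals over conformers — Student: `Gamma(α + 3K/2, β + Σ_k ‖d_ki‖²/2)`,
K: the GIG analogue with `psi = Σ_k ‖d_ki‖²` — while the α, β updates see N
scale values (one per position; using N·K terms would double-count the
mixing-density likelihood).  The mean update is the plain average of the
superposed conformers (the weights discriminate positions, not conformers).
The rotational/translational gauge freedom of the mean is fixed by centring
it at the origin and aligning its principal axes with a deterministic sign
convention.  The per-domain RMS deviation from the mean is exposed as
`ensemble_rmsd` — the "internal RMSD" precision statistic; a pairwise
inter-conformer RMSD would be ~√2 larger for Gaussian scatter, so the two
statistics must not be mixed.

## Synthetic world

The generators produce Cα chains as 3.8 Å fixed-step random walks with
direction persistence (realistic radii of gyration; no self-avoidance).  The
fits are sensitive to the displacement model, not the chain geometry, which
is why this is an adequate test bed.  Stated scenarios:

- `generate_pair`: scales from `g(s; α, β)`, default Student α = β = 1 —
  many sub-Å displacements with occasional large excursions.
- `generate_domain_motion`: default 70% contiguous core with 0.3 Å jitter,
  mobile block rotated 30° about a random axis through its centroid plus a
  20 Å shift — the domain-transition regime (a 30%-core variant covers
  large-scale refolding).
- `generate_ensemble`: 10 conformers, 60% core at 0.2 Å, tail swung about a
  hinge by N(0, 25°) angles plus 1.5 Å jitter, each conformer in a random
  global frame — the NMR-ensemble regime.

What the generators do **not** emulate: correlated (elastic-network-like)
displacement fields, anisotropic per-position covariances, sequence- or
contact-dependent stiffness, and missing residues.  A green test therefore
establishes correct inference under the stated mixture world, not
biophysical realism of any particular protein family.

## Numerical choices

- Squared residuals are floored at 1e-12 Å² in scale posteriors: keeps the
  GIG proper at zero residual and keeps degenerate (exactly rigid) inputs on
  a uniform-weight trajectory instead of an arbitrary one.
- α is confined to [1e-3, 1e3]; the EM drivers clamp at the ends (degenerate
  zero-residual input pushes the mode to +∞), the standalone update reports
  a bracket failure.
- Weighted Kabsch normalises weights by their maximum (the minimiser is
  scale-invariant) so that runaway stiffness scales cannot overflow the
  cross-covariance; collinearity is detected at singular-value ratio 1e-8
  and reported with the observed rank.
- Bessel ratios use `scipy.special.kve` (exponentially scaled) throughout;
  `∂_p log K_p` uses a central difference with h = 1e-5.
- Hyperpriors default to Gamma(0.01, 0.01) on α and β — proper but weak;
  at N ≥ 50 they shift estimates by well under 1%.

## Known limitations

- Residue correspondence is by residue number intersection; no sequence
  alignment, no insertion-code disambiguation, Cα only, standard amino
  acids only.
- The harmonic-mean evidence estimator is simple and fast but biased in
  finite samples; orderings separated by many standard errors are
  trustworthy, small gaps are not.  Thermodynamic integration would be the
  upgrade path.
- The ensemble model shares one scale per position across conformers;
  per-conformer weights and full covariance structure are out of scope.
- Published-structure analyses (e.g. chaperonin open/closed pairs or
  calmodulin NMR ensembles) run through `workflows.superpose_files` /
  `fit_ensemble_file` but require the user to supply the PDB files; none are
  bundled.
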