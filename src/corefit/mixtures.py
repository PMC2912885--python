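"""Scale-mixture models of non-rigid displacements.

A displacement vector ``d`` in 3-space is modelled as a zero-mean isotropic
Gaussian whose inverse variance (the local "stiffness" scale ``s``) is itself
random with mixing density ``g(s; alpha, beta)``:

    f(d) = ∫ N(d; 0, s⁻¹ I) g(s; α, β) ds

* ``g`` Gamma(α, rate β)      →  f is a 3-D Student t distribution
* ``g`` Inverse-Gamma(α, β)   →  f is a 3-D K distribution (Bessel tails)
* K with α = 2, β = λ²/2      →  f is the 3-D Laplace density λ³/(8π)·e^{−λ‖d‖}
* degenerate ``g`` (point mass at a fixed precision) → plain Gaussian

The heavier-than-Gaussian tails are what make the implied superposition
robust: the conditional posterior of each scale down-weights positions with
large residuals, turning the M-step into a weighted RMSD fit.

Conventions: Gamma distributions are shape/rate (β is a rate); the
Generalized Inverse Gaussian GIG(p, chi, psi) has density
``∝ s^{p−1} · exp(−(chi/s + psi·s)/2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "MODELS",
    "MixtureParams",
    "GammaPosterior",
    "GIGPosterior",
    "log_density",
    "log_density_pooled",
    "scale_posterior",
    "expected_scale",
    "sample_scale",
    "mixing_log_density",
    "draw_mixing_scales",
    "total_neg_log_likelihood",
]

MODELS = ("gauss", "student", "kdist", "laplace")

_LOG_2PI = math.log(2.0 * math.pi)
_MIN_SQ = 1e-12  # floor on ‖d‖² keeping GIG posteriors proper at zero residual


@dataclass(frozen=True)
class MixtureParams:
    """Model tag plus the shape ``alpha`` and scale ``beta`` of the mixing density.

    For ``gauss``, ``beta`` is the (isotropic) precision and ``alpha`` is
    ignored; for ``laplace``, ``beta`` is the rate λ of the exponential decay.
    """

    model: str
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise ValueError("alpha must be positive and finite")
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValueError("beta must be positive and finite")

    def as_kdist(self) -> "MixtureParams":
        """The K-family member equal to this model (Laplace: α=2, β=λ²/2)."""
        if self.model == "kdist":
            return self
        if self.model == "laplace":
            return MixtureParams("kdist", 2.0, self.beta**2 / 2.0)
        raise ValueError(f"{self.model} is not in the K family")


@dataclass(frozen=True)
class GammaPosterior:
    """Conditional posterior of a scale under the Student t model."""

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError("Gamma posterior needs positive shape and rate")


@dataclass(frozen=True)
class GIGPosterior:
    """Conditional posterior of a scale under the K model (GIG family)."""

    p: float
    chi: float
    psi: float

    def __post_init__(self) -> None:
        if not (self.chi > 0 and self.psi > 0):
            raise ValueError("GIG posterior needs positive chi and psi")


def log_density_pooled(params: MixtureParams, sq_sums, k: int = 1):
    """Log of ``∫ (s/2π)^{3k/2} exp(−s·q/2) g(s; α, β) ds`` for q = ``sq_sums``.

    With ``k=1`` and ``q=‖d‖²`` this is the displacement density ``f(d)``;
    for ``k`` conformers sharing one scale it is the pooled marginal used by
    the ensemble fit.  Vectorised over ``sq_sums``.
    """
    q = np.maximum(np.asarray(sq_sums, dtype=float), 0.0)
    h = 1.5 * k  # Gaussian exponent contributed by 3k coordinates
    a, b = params.alpha, params.beta
    if params.model == "gauss":
        tau = params.beta
        return h * (math.log(tau) - _LOG_2PI) - 0.5 * tau * q
    if params.model == "student":
        return (
            special.gammaln(a + h)
            - special.gammaln(a)
            + a * math.log(b)
            - h * _LOG_2PI
            - (a + h) * np.log(b + q / 2.0)
        )
    if params.model == "laplace" and k == 1:
        lam = params.beta
        return 3.0 * math.log(lam) - math.log(8.0 * math.pi) - lam * np.sqrt(q)
    # K family via the GIG normalisation integral, in log space
    kp = params.as_kdist()
    a, b = kp.alpha, kp.beta
    p = h - a
    q = np.maximum(q, _MIN_SQ)
    eta = np.sqrt(2.0 * b * q)
    log_bessel = np.log(special.kve(p, eta)) - eta  # kve = K_p(x)·e^x
    return (
        -h * _LOG_2PI
        + a * math.log(b)
        - special.gammaln(a)
        + math.log(2.0)
        + 0.5 * p * (np.log(2.0 * b) - np.log(q))
        + log_bessel
    )


def log_density(params: MixtureParams, displacement_norm):
    """Log of the 3-D displacement density ``f(d)`` at ``‖d‖``; vectorised."""
    r = np.asarray(displacement_norm, dtype=float)
    if np.any(r < 0):
        raise ValueError("displacement norms must be non-negative")
    return log_density_pooled(params, r**2, k=1)


def scale_posterior(params: MixtureParams, displacement_norm: float, pooled_k: int = 1):
    """Conditional posterior of the local scale given a residual.

    Student t: ``Gamma(α + 3k/2, β + q/2)``; K: ``GIG(3k/2 − α, 2β, q)`` with
    ``q`` the (pooled) squared residual norm — in the product
    ``N(d; 0, s⁻¹) · InvGamma(s; α, β)`` the ``1/s`` coefficient is ``2β`` and
    the ``s`` coefficient is ``q``, which fixes the (p, chi, psi) order.
    Gaussian and Laplace expose no per-position latent scale through this API.
    """
    if params.model not in ("student", "kdist"):
        raise ValueError(f"model {params.model!r} has no per-position scale posterior")
    q = max(float(displacement_norm) ** 2 if pooled_k == 1 else float(displacement_norm), _MIN_SQ)
    h = 1.5 * pooled_k
    if params.model == "student":
        return GammaPosterior(params.alpha + h, params.beta + q / 2.0)
    return GIGPosterior(h - params.alpha, 2.0 * params.beta, q)


def _gig_mean(p, chi, psi):
    eta = np.sqrt(chi * psi)
    # kve ratios are overflow-safe; the e^x factors cancel
    return np.sqrt(chi / psi) * special.kve(p + 1.0, eta) / special.kve(p, eta)


def expected_scale(post) -> float:
    """Posterior mean of the scale: ``a/b`` for Gamma(a, b);
    ``sqrt(chi/psi)·K_{p+1}(η)/K_p(η)`` with ``η=sqrt(chi·psi)`` for the GIG."""
    if isinstance(post, GammaPosterior):
        return post.shape / post.rate
    if isinstance(post, GIGPosterior):
        val = float(_gig_mean(post.p, post.chi, post.psi))
        if not np.isfinite(val) or val <= 0:
            raise FloatingPointError(f"non-finite GIG mean for {post}")
        return val
    raise TypeError(f"unsupported posterior {type(post).__name__}")


def sample_scale(post, rng: np.random.Generator) -> float:
    """One draw from a scale posterior (Gamma directly, GIG via scipy)."""
    if isinstance(post, GammaPosterior):
        return float(rng.gamma(post.shape) / post.rate)
    if isinstance(post, GIGPosterior):
        eta = math.sqrt(post.chi * post.psi)
        return float(
            stats.geninvgauss.rvs(
                post.p, eta, scale=math.sqrt(post.chi / post.psi), random_state=rng
            )
        )
    raise TypeError(f"unsupported posterior {type(post).__name__}")


def mixing_log_density(params: MixtureParams, s):
    """Log of the mixing density g(s): Gamma (student) or Inverse Gamma (K)."""
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("scales must be positive")
    if params.model == "student":
        return stats.gamma.logpdf(s, params.alpha, scale=1.0 / params.beta)
    if params.model in ("kdist", "laplace"):
        kp = params.as_kdist()
        return stats.invgamma.logpdf(s, kp.alpha, scale=kp.beta)
    raise ValueError(f"model {params.model!r} has no mixing density")


def draw_mixing_scales(params: MixtureParams, n: int, rng: np.random.Generator):
    """Draw n scales from g(s) — the generative direction, used by the
    synthetic-data module.  For gauss all scales equal the fixed precision."""
    if params.model == "gauss":
        return np.full(n, params.beta)
    if params.model == "student":
        return rng.gamma(params.alpha, 1.0 / params.beta, size=n)
    kp = params.as_kdist()
    return kp.beta / rng.gamma(kp.alpha, 1.0, size=n)


def total_neg_log_likelihood(params: MixtureParams, disp) -> float:
    """Negative log-likelihood ``−Σ_i log f(d_i)`` of a displacement set."""
    norms = getattr(disp, "norms", None)
    if norms is None:
        norms = np.asarray(disp, dtype=float)
    return float(-np.sum(log_density(params, norms)))
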