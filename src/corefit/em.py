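"""Expectation-Maximization fitting of the robust superposition model.

One EM cycle (deterministic branch of the iterative scheme):

  1. weighted Kabsch fit of the mobile structure with the current scales,
  2. residual displacements under the new transform,
  3. CM updates of the mixing parameters: β from its conjugate Gamma
     conditional (MAP maximizer, so the tracked objective stays monotone)
     and α as the root of the conditional score on the exact E-step
     statistic E[log s],
  4. E-step: replace each scale by its conditional posterior mean
     (Gamma mean for Student t, Bessel-ratio GIG mean for the K model).

The Gaussian model needs no iteration (classical Kabsch + precision MLE);
the Laplace model runs the K machinery with its shape pinned at α = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

from .geometry import RigidTransform, displacements, weighted_superpose
from .mixtures import (
    MixtureParams,
    expected_scale,
    scale_posterior,
    total_neg_log_likelihood,
)

__all__ = [
    "Hyperprior",
    "FitOptions",
    "FitResult",
    "e_step",
    "m_step_transform",
    "update_beta",
    "update_alpha",
    "fit_em",
]

_ALPHA_BRACKET = (1e-3, 1e3)


@dataclass(frozen=True)
class Hyperprior:
    """Weak Gamma hyperpriors on α and β (shape/rate); proper but diffuse."""

    alpha_shape: float = 0.01
    alpha_rate: float = 0.01
    beta_shape: float = 0.01
    beta_rate: float = 0.01

    def __post_init__(self) -> None:
        if min(self.alpha_shape, self.alpha_rate, self.beta_shape, self.beta_rate) <= 0:
            raise ValueError("hyperprior parameters must be positive")

    def log_density(self, alpha: float, beta: float) -> float:
        la = (
            self.alpha_shape * np.log(self.alpha_rate)
            - special.gammaln(self.alpha_shape)
            + (self.alpha_shape - 1) * np.log(alpha)
            - self.alpha_rate * alpha
        )
        lb = (
            self.beta_shape * np.log(self.beta_rate)
            - special.gammaln(self.beta_shape)
            + (self.beta_shape - 1) * np.log(beta)
            - self.beta_rate * beta
        )
        return float(la + lb)


@dataclass(frozen=True)
class FitOptions:
    max_iterations: int = 200
    tolerance: float = 1e-8
    init_scales: str = "uniform"  # or "random"
    seed: int = 0
    hyperprior: Hyperprior = field(default_factory=Hyperprior)
    n_starts: int = 1

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.init_scales not in ("uniform", "random"):
            raise ValueError("init_scales must be 'uniform' or 'random'")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    transform: RigidTransform
    scales: np.ndarray
    params: MixtureParams
    nll_trace: np.ndarray
    iterations: int
    converged: bool


def e_step(params: MixtureParams, disp) -> np.ndarray:
    """Replace each latent scale by its conditional posterior mean."""
    norms = disp.norms if hasattr(disp, "norms") else np.asarray(disp, dtype=float)
    return np.array(
        [expected_scale(scale_posterior(params, r)) for r in norms], dtype=float
    )


def _dlogK_dp(p: float, eta, h: float = 1e-5):
    """Derivative of log K_p(eta) with respect to the order p (central diff)."""
    return (np.log(special.kve(p + h, eta)) - np.log(special.kve(p - h, eta))) / (2 * h)


def _posterior_expectations(params: MixtureParams, norms, pooled_k: int = 1):
    """E[s], E[1/s] and E[log s] under the conditional scale posteriors.

    These are the sufficient statistics of the exact E-step: the weighted fit
    consumes E[s], the β M-step E[s] (student) or E[1/s] (K), and the α
    M-step E[log s].
    """
    from .mixtures import _MIN_SQ

    q = np.maximum(np.asarray(norms, dtype=float) ** 2, _MIN_SQ)
    h = 1.5 * pooled_k
    if params.model == "student":
        shape = params.alpha + h
        rate = params.beta + q / 2.0
        return {
            "mean": shape / rate,
            "inv_mean": rate / (shape - 1.0) if shape > 1.0 else None,
            "log_mean": special.digamma(shape) - np.log(rate),
        }
    if params.model == "kdist":
        chi = 2.0 * params.beta
        psi = q
        p = h - params.alpha
        eta = np.sqrt(chi * psi)
        kr = special.kve(p + 1.0, eta) / special.kve(p, eta)
        mean = np.sqrt(chi / psi) * kr
        # 1/s ~ GIG(-p, psi, chi): E[1/s] = sqrt(psi/chi)·K_{p-1}/K_p = kr·psi/chi − 2p/chi
        inv_mean = np.sqrt(psi / chi) * special.kve(p - 1.0, eta) / special.kve(p, eta)
        log_mean = 0.5 * (np.log(chi) - np.log(psi)) + _dlogK_dp(p, eta)
        return {"mean": mean, "inv_mean": inv_mean, "log_mean": log_mean}
    raise ValueError(f"no scale posterior for model {params.model!r}")


def m_step_transform(pair, scales) -> RigidTransform:
    """Weighted RMSD fit with the scales as positional weights."""
    return weighted_superpose(pair, scales)


def update_beta(
    params: MixtureParams, scales, hyper: Hyperprior | None = None
) -> float:
    """Posterior-mean update of β given the scales (conjugate Gamma posterior).

    student: (N·α + a_β) / (Σ s_i + b_β);  K: (N·α + a_β) / (Σ 1/s_i + b_β).
    """
    hyper = hyper or Hyperprior()
    s = np.asarray(scales, dtype=float)
    n = s.size
    if params.model == "student":
        return float((n * params.alpha + hyper.beta_shape) / (s.sum() + hyper.beta_rate))
    if params.model == "kdist":
        return float(
            (n * params.alpha + hyper.beta_shape) / ((1.0 / s).sum() + hyper.beta_rate)
        )
    raise ValueError(f"no beta update for model {params.model!r}")


def _alpha_score(model: str, beta: float, log_s_sum: float, n: int, hyper: Hyperprior):
    sign = 1.0 if model == "student" else -1.0

    def score(a):
        return (
            n * np.log(beta)
            - n * special.digamma(a)
            + sign * log_s_sum
            + (hyper.alpha_shape - 1.0) / a
            - hyper.alpha_rate
        )

    return score


def update_alpha(
    params: MixtureParams, scales, hyper: Hyperprior | None = None, clamp: bool = False
) -> float:
    """Root of the conditional score of α (digamma equation), solved by brentq.

    The conditional log-posterior of α given scales and β is strictly concave
    under the Gamma hyperprior, so the score has at most one root; absence of
    a sign change in the bracket [1e-3, 1e3] is reported as an error unless
    ``clamp`` is set, in which case the bracket end nearest the mode is
    returned (the EM drivers clamp, so that degenerate zero-residual inputs —
    where the conditional mode runs away — still terminate).
    """
    hyper = hyper or Hyperprior()
    if params.model not in ("student", "kdist"):
        raise ValueError(f"no alpha update for model {params.model!r}")
    s = np.asarray(scales, dtype=float)
    score = _alpha_score(params.model, params.beta, float(np.log(s).sum()), s.size, hyper)
    lo, hi = _ALPHA_BRACKET
    flo, fhi = score(lo), score(hi)
    if flo < 0 or fhi > 0:
        if clamp:
            return lo if flo < 0 else hi
        raise RuntimeError(
            f"no root of the alpha score in [{lo}, {hi}]: score({lo})={flo:.3g}, "
            f"score({hi})={fhi:.3g}"
        )
    return float(optimize.brentq(score, lo, hi, xtol=1e-10, rtol=1e-12))


def _objective(pair, transform, params, hyper) -> float:
    """Negative log posterior over (R, t, α, β) with scales marginalised."""
    d = displacements(pair, transform)
    nll = total_neg_log_likelihood(params, d)
    if params.model in ("student", "kdist"):
        nll -= hyper.log_density(params.alpha, params.beta)
    return float(nll)


def _fit_gauss(pair, opts: FitOptions) -> FitResult:
    transform = weighted_superpose(pair)  # uniform weights: classical Kabsch
    d = displacements(pair, transform)
    precision = 3.0 * pair.n / float((d.norms**2).sum() + 1e-30)
    params = MixtureParams("gauss", 1.0, precision)
    nll = total_neg_log_likelihood(params, d)
    return FitResult(
        transform=transform,
        scales=np.full(pair.n, precision),
        params=params,
        nll_trace=np.array([nll]),
        iterations=1,
        converged=True,
    )


def _init_scales(n: int, opts: FitOptions, rng: np.random.Generator) -> np.ndarray:
    if opts.init_scales == "uniform":
        return np.ones(n)
    return rng.gamma(1.0, 1.0, size=n) + 1e-3


def _alpha_root(model, beta, n, log_sum, hyper) -> float:
    score = _alpha_score(model, beta, log_sum, n, hyper)
    lo, hi = _ALPHA_BRACKET
    if score(lo) < 0:
        return lo
    if score(hi) > 0:
        return hi
    return float(optimize.brentq(score, lo, hi, xtol=1e-10, rtol=1e-12))


def _fit_heavy(pair, model: str, opts: FitOptions, scales0: np.ndarray) -> FitResult:
    fixed_alpha = 2.0 if model == "laplace" else None
    work_model = "kdist" if model == "laplace" else model
    params = MixtureParams(work_model, fixed_alpha or 1.0, 1.0)
    scales = scales0.copy()
    trace = []
    converged = False
    it = 0
    transform = None
    hyper = opts.hyperprior
    n = pair.n
    for it in range(1, opts.max_iterations + 1):
        transform = m_step_transform(pair, scales)
        d = displacements(pair, transform)
        # exact E-step sufficient statistics; the α M-step needs E[log s]
        # (conditioning it on point scales is biased and can run away)
        exp = _posterior_expectations(params, d.norms)
        if work_model == "student":
            denom = float(np.sum(exp["mean"]))
        else:
            denom = float(np.sum(exp["inv_mean"]))
        # MAP maximizer (shape − 1), not the posterior mean: keeps the
        # tracked negative log posterior exactly monotone
        shape = max(n * params.alpha + hyper.beta_shape - 1.0, 1e-6)
        beta = shape / (denom + hyper.beta_rate)
        params = replace(params, beta=beta)
        if fixed_alpha is None:
            alpha = _alpha_root(
                work_model, beta, n, float(np.sum(exp["log_mean"])), hyper
            )
            params = replace(params, alpha=alpha)
        scales = e_step(params, d)
        trace.append(_objective(pair, transform, params, opts.hyperprior))
        if len(trace) > 1:
            prev, cur = trace[-2], trace[-1]
            if abs(prev - cur) <= opts.tolerance * max(1.0, abs(prev)):
                converged = True
                break
    if model == "laplace":
        params = MixtureParams("laplace", 1.0, np.sqrt(2.0 * params.beta))
    return FitResult(
        transform=transform,
        scales=scales,
        params=params,
        nll_trace=np.asarray(trace),
        iterations=it,
        converged=converged,
    )


def fit_em(pair, model: str = "student", opts: FitOptions | None = None) -> FitResult:
    """Fit the robust superposition model by EM.

    Parameters
    ----------
    pair : MatchedPair
        Matched coordinate sets, x mobile and y reference.
    model : {"gauss", "student", "kdist", "laplace"}
        Displacement model.  ``gauss`` is the classical (non-iterative) RMSD
        fit; the heavy-tailed models iterate scale/transform/parameter
        updates.
    opts : FitOptions
        Iteration control, initial scales and hyperpriors.  ``n_starts > 1``
        restarts from random scale initialisations and keeps the
        highest-posterior solution, which matters for bimodal cases such as
        two-domain proteins where either domain can serve as the core.
    """
    opts = opts or FitOptions()
    if model == "gauss":
        return _fit_gauss(pair, opts)
    if model not in ("student", "kdist", "laplace"):
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(opts.seed)
    best = None
    for start in range(opts.n_starts):
        if start == 0:
            scales0 = _init_scales(pair.n, opts, rng)
        else:
            scales0 = rng.gamma(1.0, 1.0, size=pair.n) + 1e-3
        result = _fit_heavy(pair, model, opts, scales0)
        if best is None or result.nll_trace[-1] < best.nll_trace[-1]:
            best = result
    return best
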