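"""Robust superposition of conformer ensembles onto an estimated mean structure.

NMR structures come as ensembles of conformers; assessing their precision
requires superposing all conformers into a common frame.  Here every
conformer k gets its own rigid transform onto a latent mean structure, while
all conformers share one scale s_i per position ("local stiffness").  The EM
alternation is the pooled extension of the pairwise fit:

  1. weighted superposition of each conformer onto the current mean,
  2. mean update as the plain average of the superposed conformers,
  3. E-step with residuals pooled over conformers — under the Student t
     model the scale posterior of position i is
     Gamma(α + 3K/2, β + Σ_k ||d_ki||²/2) for K conformers, and the GIG
     analogue under the K model,
  4. conjugate β update and root-finding α update on the shared scales.

The rotational/translational gauge freedom of the mean is fixed by centring
it at the origin and aligning its principal axes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .em import FitOptions, _alpha_root, _posterior_expectations
from .geometry import RigidTransform, apply_transform, weighted_superpose
from .io_structures import CoordinateSet, MatchedPair
from .mixtures import (
    MixtureParams,
    expected_scale,
    log_density_pooled,
    scale_posterior,
)

__all__ = ["EnsembleFit", "fit_ensemble", "ensemble_rmsd"]


@dataclass(frozen=True)
class EnsembleFit:
    mean_structure: CoordinateSet
    transforms: tuple
    superposed: tuple  # conformers mapped into the mean frame
    scales: np.ndarray
    params: MixtureParams
    nll_trace: np.ndarray
    iterations: int
    converged: bool


def _check_conformers(conformers) -> None:
    if len(conformers) < 2:
        raise ValueError(f"need at least 2 conformers, got {len(conformers)}")
    ids0 = conformers[0].residue_ids
    for k, c in enumerate(conformers[1:], start=1):
        if not np.array_equal(c.residue_ids, ids0):
            raise ValueError(f"conformer {k} has a different residue set than conformer 0")


def _principal_axis_gauge(mean: CoordinateSet) -> RigidTransform:
    """Gauge transform centring the mean and aligning its principal axes."""
    pos = mean.positions
    centroid = pos.mean(axis=0)
    centred = pos - centroid
    _, vecs = np.linalg.eigh(centred.T @ centred)
    V = vecs[:, ::-1]  # descending variance
    for j in range(3):  # deterministic sign: largest component positive
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return RigidTransform(V.T, -V.T @ centroid)


def _pooled_objective(params, q, k, hyper) -> float:
    nll = -float(np.sum(log_density_pooled(params, q, k=k)))
    if params.model in ("student", "kdist"):
        nll -= hyper.log_density(params.alpha, params.beta)
    return nll


def _fit_once(conformers, model, opts: FitOptions, scales0) -> EnsembleFit:
    K = len(conformers)
    n = len(conformers[0])
    fixed_alpha = 2.0 if model == "laplace" else None
    gauss = model == "gauss"
    work_model = {"laplace": "kdist", "gauss": "student"}.get(model, model)
    params = MixtureParams(work_model, fixed_alpha or 1.0, 1.0)

    scales = scales0.copy()
    mean = conformers[0]
    trace: list[float] = []
    converged = False
    it = 0
    transforms = [RigidTransform.identity()] * K
    for it in range(1, opts.max_iterations + 1):
        weights = np.ones(n) if gauss else scales
        transforms = [
            weighted_superpose(MatchedPair(c, mean), weights) for c in conformers
        ]
        moved = [apply_transform(T, c) for T, c in zip(transforms, conformers)]
        mean_pos = np.mean([m.positions for m in moved], axis=0)
        mean = CoordinateSet(
            mean_pos, mean.residue_ids, mean.chain_id, "ensemble mean",
            mean.residue_names,
        )
        q = np.sum(
            [np.sum((m.positions - mean_pos) ** 2, axis=1) for m in moved], axis=0
        )
        if gauss:
            precision = 3.0 * n * K / float(q.sum() + 1e-30)
            params = MixtureParams("gauss", 1.0, precision)
            scales = np.full(n, precision)
            obj = _pooled_objective(params, q, K, opts.hyperprior)
        else:
            # pooled E-step sufficient statistics, then MAP CM steps for β, α
            hyper = opts.hyperprior
            exp = _posterior_expectations(params, np.sqrt(q), pooled_k=K)
            if work_model == "student":
                denom = float(np.sum(exp["mean"]))
            else:
                denom = float(np.sum(exp["inv_mean"]))
            shape = max(n * params.alpha + hyper.beta_shape - 1.0, 1e-6)
            params = replace(params, beta=shape / (denom + hyper.beta_rate))
            if fixed_alpha is None:
                params = replace(
                    params,
                    alpha=_alpha_root(
                        work_model, params.beta, n,
                        float(np.sum(exp["log_mean"])), hyper,
                    ),
                )
            scales = np.array(
                [
                    expected_scale(scale_posterior(params, qi, pooled_k=K))
                    for qi in q
                ]
            )
            obj = _pooled_objective(params, q, K, opts.hyperprior)
        trace.append(obj)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) <= opts.tolerance * max(
            1.0, abs(trace[-2])
        ):
            converged = True
            break

    gauge = _principal_axis_gauge(mean)
    mean = apply_transform(gauge, mean)
    transforms = tuple(gauge.compose(T) for T in transforms)
    moved = tuple(apply_transform(T, c) for T, c in zip(transforms, conformers))
    if model == "laplace":
        params = MixtureParams("laplace", 1.0, float(np.sqrt(2.0 * params.beta)))
    return EnsembleFit(
        mean_structure=mean,
        transforms=transforms,
        superposed=moved,
        scales=scales,
        params=params,
        nll_trace=np.asarray(trace),
        iterations=it,
        converged=converged,
    )


def fit_ensemble(conformers, model: str = "student", opts: FitOptions | None = None) -> EnsembleFit:
    """Superpose >= 2 conformers onto an estimated mean structure.

    ``opts.n_starts > 1`` restarts from random shared-scale initialisations
    and keeps the highest-posterior solution; two-domain proteins (the
    calmodulin situation) have genuinely bimodal posteriors where either
    domain can serve as the superposition core.
    """
    opts = opts or FitOptions()
    _check_conformers(conformers)
    if model not in ("gauss", "student", "kdist", "laplace"):
        raise ValueError(f"unknown model {model!r}")
    n = len(conformers[0])
    rng = np.random.default_rng(opts.seed)
    best = None
    for start in range(opts.n_starts):
        if start == 0 and opts.init_scales == "uniform":
            scales0 = np.ones(n)
        else:
            scales0 = rng.gamma(1.0, 1.0, size=n) + 1e-3
        fit = _fit_once(conformers, model, opts, scales0)
        if best is None or fit.nll_trace[-1] < best.nll_trace[-1]:
            best = fit
    return best


def ensemble_rmsd(fit: EnsembleFit, subset=None) -> float:
    """RMS deviation of superposed conformers from the mean structure.

    Root-mean-square over conformers and (subset) positions; the per-domain
    version of this statistic is the "internal RMSD" quoted for NMR
    ensembles.
    """
    ids = fit.mean_structure.residue_ids
    if subset is None:
        mask = np.ones(ids.size, dtype=bool)
    else:
        mask = np.isin(ids, np.asarray(list(subset), dtype=int))
        if not mask.any():
            raise ValueError("subset selects no residues")
    sq = [
        np.sum((m.positions[mask] - fit.mean_structure.positions[mask]) ** 2, axis=1)
        for m in fit.superposed
    ]
    return float(np.sqrt(np.mean(np.concatenate(sq))))
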