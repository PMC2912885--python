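"""Rigid-body transforms, weighted least-squares superposition and RMSD utilities.

The convention throughout the package is that a :class:`RigidTransform` maps
the *mobile* structure ``x`` onto the *reference* structure ``y``:

    y_i ≈ R @ x_i + t

The workhorse is :func:`weighted_superpose`, the weighted Kabsch fit that the
EM algorithm calls in every M-step: it returns the global minimiser of
``sum_i w_i * ||y_i - R x_i - t||^2`` over proper rotations and translations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "Displacements",
    "apply_transform",
    "displacements",
    "weighted_superpose",
    "rmsd",
    "rotation_angle",
]

_ORTHO_TOL = 1e-8


class DegenerateCoordinatesError(ValueError):
    """Raised when the point configuration does not pin down a rotation."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid-body transform: rotation ``R`` (det +1) plus translation ``t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("transform entries must be finite")
        if np.abs(R.T @ R - np.eye(3)).max() > _ORTHO_TOL:
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, positions: np.ndarray) -> np.ndarray:
        """Map an (n, 3) coordinate array: ``R @ x + t`` row-wise."""
        return np.asarray(positions, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class Displacements:
    """Non-rigid residual vectors ``d_i = y_i - R x_i - t`` with cached norms."""

    vectors: np.ndarray
    norms: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "norms", np.linalg.norm(v, axis=1))

    def __len__(self) -> int:
        return self.vectors.shape[0]


def apply_transform(transform: RigidTransform, coords):
    """Transform a CoordinateSet (or bare array), keeping residue labelling."""
    from .io_structures import CoordinateSet

    if isinstance(coords, CoordinateSet):
        return CoordinateSet(
            positions=transform.apply(coords.positions),
            residue_ids=coords.residue_ids,
            chain_id=coords.chain_id,
            label=coords.label,
            residue_names=coords.residue_names,
        )
    return transform.apply(np.asarray(coords, dtype=float))


def displacements(pair, transform: RigidTransform) -> Displacements:
    """Residuals ``d_i = y_i - (R x_i + t)`` for a matched pair."""
    return Displacements(pair.y.positions - transform.apply(pair.x.positions))


def weighted_superpose(pair, weights=None) -> RigidTransform:
    """Weighted Kabsch superposition of ``pair.x`` onto ``pair.y``.

    Minimises ``sum_i w_i ||y_i - R x_i - t||^2`` exactly, via SVD of the
    weighted cross-covariance with the usual sign correction that excludes
    reflections.  Uniform weights reduce to the classical unweighted fit; the
    result is invariant to rescaling all weights by a positive constant.

    Parameters
    ----------
    pair : MatchedPair
        Matched coordinate sets (x mobile, y reference), n >= 3.
    weights : array-like of positive floats, optional
        Per-position weights (the local scales ``s_i``); uniform if omitted.
    """
    x = pair.x.positions
    y = pair.y.positions
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 matched positions, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights length must equal the number of positions")
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive and finite")
        w = w / w.max()  # result is scale-invariant; guards huge-weight overflow
    wsum = w.sum()
    xc = (w[:, None] * x).sum(axis=0) / wsum
    yc = (w[:, None] * y).sum(axis=0) / wsum
    xt = x - xc
    yt = y - yc

    # rank check on the weighted mobile cloud: collinear points leave the
    # rotation about the line undetermined
    sv = np.linalg.svd(np.sqrt(w)[:, None] * xt, compute_uv=False)
    rank = int(np.sum(sv > 1e-8 * sv[0])) if sv[0] > 0 else 0
    if rank < 2:
        raise DegenerateCoordinatesError(
            f"degenerate configuration: weighted coordinate rank {rank} < 2"
        )

    A = (w[:, None] * yt).T @ xt  # 3x3 weighted cross-covariance, A = sum w y~ x~^T
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = yc - R @ xc
    return RigidTransform(R, t)


def cross_moment(pair, weights) -> np.ndarray:
    """Weighted cross-moment ``A = sum_i w_i y~_i x~_i^T`` of centred coordinates.

    This is the matrix whose trace functional ``exp(tr(A^T R))`` is the
    conditional posterior of the rotation in the Gibbs sampler.
    """
    x = pair.x.positions
    y = pair.y.positions
    w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    xt = x - (w[:, None] * x).sum(axis=0) / wsum
    yt = y - (w[:, None] * y).sum(axis=0) / wsum
    return (w[:, None] * yt).T @ xt


def rmsd(pair, transform: RigidTransform, subset=None) -> float:
    """RMSD over matched positions after applying ``transform`` to ``x``.

    ``subset`` restricts the average to the given residue ids (iterable of
    ints); by default all matched positions contribute.
    """
    d = displacements(pair, transform)
    if subset is None:
        sq = d.norms**2
    else:
        wanted = np.isin(pair.x.residue_ids, np.asarray(list(subset), dtype=int))
        if not wanted.any():
            raise ValueError("subset selects no matched residues")
        sq = d.norms[wanted] ** 2
    return float(np.sqrt(sq.mean()))


def rotation_angle(transform: RigidTransform) -> float:
    """Rotation angle in degrees, in [0, 180], from the trace of R."""
    cos = (np.trace(transform.rotation) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
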