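"""Signal-subspace machinery: data covariance, automatic rank selection, and
the MUSIC localizer.

The sensor covariance ``C = M Mᵀ`` is eigendecomposed and the signal subspace
is chosen by scanning the normalized eigenvalue spectrum for the first gap
that falls below a relative criterion ``ε``.  The localizer scores how well a
candidate topography ``l`` lies inside the (possibly out-projected) signal
subspace: ``μ = ‖P Q l‖² / ‖Q l‖² ∈ [0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubspaceModel",
    "data_covariance",
    "select_signal_rank",
    "signal_projector",
    "localizer",
    "decompose",
]

#: relative eigenvalue-gap criterion for signal-subspace selection
DEFAULT_EPSILON = 0.01


@dataclass
class SubspaceModel:
    """Eigendecomposition of a sensor covariance with a selected signal rank."""

    covariance: np.ndarray
    eigvecs: np.ndarray  # orthonormal columns, leading first
    eigvals: np.ndarray  # nonincreasing
    signal_rank: int
    epsilon: float

    @property
    def projector(self) -> np.ndarray:
        return signal_projector(self.eigvecs, self.signal_rank)


def data_covariance(
    data: np.ndarray, demean: bool = False, scale: bool = False
) -> np.ndarray:
    """Sensor covariance ``C = M Mᵀ``.

    By default the raw outer product is used (no mean removal, no ``1/t``
    scaling); the localizer and the rank rule are invariant to both, so the
    flags are cosmetic.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 1:
        raise ValueError("data must be a (q, t) matrix with t >= 1")
    if demean:
        data = data - data.mean(axis=1, keepdims=True)
    c = data @ data.T
    if scale:
        c = c / data.shape[1]
    return c


def select_signal_rank(eigvals: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> int:
    """Number of leading eigenvalues attributed to the signal subspace.

    Eigenvalues are normalized by the largest; the signal subspace is the
    contiguous leading block with ``d̃_i >= epsilon``, i.e. the subspace ends
    just before the first normalized eigenvalue that falls below the relative
    criterion.  A spectrum that never falls below ``epsilon`` gives rank
    ``q``; the rank is never smaller than 1.

    This deliberately errs toward overestimating the rank (keeping weak
    sources inside the subspace): a drop-based gap rule cuts the subspace at
    internal plateaus whenever two sources have similar eigenvalues, which
    silently discards the weaker half of the spectrum.
    """
    d = np.asarray(eigvals, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("eigvals must be a nonempty 1-D array")
    if np.any(np.diff(d) > 1e-10 * max(abs(d).max(), 1.0)):
        raise ValueError("eigvals must be nonincreasing")
    d = np.clip(d, 0.0, None)
    if d[0] <= 0:
        raise ValueError("all eigenvalues are zero: no signal")
    dn = d / d[0]
    return max(int(np.sum(dn >= epsilon)), 1)


def signal_projector(eigvecs: np.ndarray, signal_rank: int) -> np.ndarray:
    """Orthogonal projector onto the span of the leading eigenvectors."""
    u = np.asarray(eigvecs, dtype=float)
    if not 1 <= signal_rank <= u.shape[1]:
        raise ValueError(f"signal_rank {signal_rank} out of range [1, {u.shape[1]}]")
    us = u[:, :signal_rank]
    return us @ us.T


def localizer(
    projector: np.ndarray,
    out_projector: np.ndarray | None,
    gain_columns: np.ndarray,
) -> np.ndarray:
    """MUSIC localizer score for every gain column.

    ``μ_j = ‖P Q l_j‖² / ‖Q l_j‖²``.  ``out_projector=None`` means plain MUSIC
    (``Q = I``).  Columns effectively annihilated by ``Q`` (``‖Q l‖²`` below
    1e-12 of ``‖l‖²``) score 0: they are already fully explained by the
    selected topographies and must not be re-selected.
    """
    g = np.asarray(gain_columns, dtype=float)
    if g.ndim != 2:
        raise ValueError("gain_columns must be 2-D (q, m)")
    p = np.asarray(projector, dtype=float)
    if p.shape != (g.shape[0], g.shape[0]):
        raise ValueError("projector shape does not match gain columns")
    col_sq = np.einsum("ij,ij->j", g, g)
    qg = g if out_projector is None else out_projector @ g
    den = np.einsum("ij,ij->j", qg, qg)
    pqg = p @ qg
    num = np.einsum("ij,ij->j", pqg, pqg)
    alive = den > 1e-12 * np.where(col_sq > 0, col_sq, 1.0)
    mu = np.zeros(g.shape[1])
    mu[alive] = num[alive] / den[alive]
    return mu


def decompose(
    covariance: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> SubspaceModel:
    """Eigendecompose a covariance (leading eigenpairs first) and select rank."""
    c = np.asarray(covariance, dtype=float)
    c = 0.5 * (c + c.T)
    vals, vecs = np.linalg.eigh(c)
    vals = vals[::-1]
    vecs = vecs[:, ::-1]
    rank = select_signal_rank(vals, epsilon)
    return SubspaceModel(
        covariance=c, eigvecs=vecs, eigvals=vals, signal_rank=rank, epsilon=epsilon
    )
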