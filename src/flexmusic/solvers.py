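"""Recursive subspace solvers for the M/EEG inverse problem.

Implements the recursive candidate-selection family:

* RAP-MUSIC — re-decompose the out-projected covariance each recursion and
  pick the single dipole maximizing the localizer.
* TRAP-MUSIC — RAP plus subspace truncation: at recursion ``i`` only the
  leading ``ñ − i`` components of the projected subspace are retained, which
  suppresses residual variance from earlier recursions (the "RAP dilemma").
* FLEX-MUSIC — the candidate set is widened from single dipoles to smooth
  dipole clusters of increasing graph radius (the smoothness dictionary); the
  argmax is taken jointly over (order k, center p), so both location and
  spatial extent are estimated.  No truncation is applied.

All three stop when the localizer maximum falls below a threshold (default
0.975), when the iteration budget is reached, or when the remaining subspace
is numerically exhausted.  The selected patches accumulate into a diagonal
source covariance ``S`` and the final current estimate is the weighted
minimum-norm solution ``Ĵ = S Lᵀ (L S Lᵀ + λI)⁻¹ M``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .source_space import LeadField, SmoothnessDictionary
from .subspace import (
    DEFAULT_EPSILON,
    data_covariance,
    decompose,
    localizer,
    select_signal_rank,
    signal_projector,
)

__all__ = [
    "Candidate",
    "CandidateSet",
    "SourceEstimate",
    "out_projector",
    "music_oneshot",
    "rap_music",
    "trap_music",
    "flex_music",
    "wmne_reconstruct",
    "apply_solver",
    "save_estimate",
    "load_estimate",
    "SOLVER_NAMES",
]

#: default localizer-peak stopping threshold
DEFAULT_THRESHOLD = 0.975
#: default relative Tikhonov ridge for the weighted minimum-norm step
DEFAULT_RIDGE = 1e-6

STOP_BELOW_THRESHOLD = "below_threshold"
STOP_MAX_ITER = "max_iter"
STOP_RANK_EXHAUSTED = "rank_exhausted"


@dataclass
class Candidate:
    """One selected source: a dipole (order 1) or a dipole cluster (order > 1)."""

    center_index: int
    order: int
    topography: np.ndarray  # length-q sensor pattern of the patch
    patch_weights: np.ndarray  # length-p spatial profile (column of G_k)
    peak_score: float


@dataclass
class CandidateSet:
    """Ordered result of a recursive scan plus the accumulated source model."""

    candidates: list[Candidate]
    topographies: np.ndarray  # (q, i) matrix B
    out_projector: np.ndarray  # (q, q) final Q
    source_cov_diag: np.ndarray  # length-p diagonal of S
    stop_reason: str
    peak_history: list[float] = field(default_factory=list)

    @property
    def source_cov(self) -> np.ndarray:
        """The p×p (diagonal) source covariance S."""
        return np.diag(self.source_cov_diag)

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass
class SourceEstimate:
    """Estimated dipole currents (p × t, nAm) with selection provenance."""

    currents: np.ndarray
    candidate_set: CandidateSet


def out_projector(topographies: np.ndarray) -> np.ndarray:
    """Projector onto the orthogonal complement of the selected topographies.

    ``Q = I − B B†`` with ``B†`` the Moore-Penrose pseudoinverse; symmetric,
    idempotent and ``Q B ≈ 0``.  An empty ``B`` gives the identity.
    """
    b = np.asarray(topographies, dtype=float)
    if b.ndim == 1:
        b = b[:, None]
    q = b.shape[0]
    if b.shape[1] == 0:
        return np.eye(q)
    return np.eye(q) - b @ np.linalg.pinv(b)


def music_oneshot(
    data: np.ndarray,
    lead: LeadField,
    criterion: float = 0.95,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[np.ndarray, np.ndarray]:
    """One-shot MUSIC scan: localizer over all dipoles plus an active mask.

    Returns ``(mu, mask)`` where ``mask = mu >= criterion``.
    """
    if not 0 < criterion:
        raise ValueError("criterion must be positive")
    model = decompose(data_covariance(data), epsilon)
    mu = localizer(model.projector, None, lead.gain)
    return mu, mu >= criterion


def _recursive_scan(
    data: np.ndarray,
    gains: list[np.ndarray],
    operators: list[np.ndarray] | None,
    n_dipoles: int,
    threshold: float,
    epsilon: float,
    max_iter: int | None,
    truncate: bool,
) -> CandidateSet:
    """Shared recursion for RAP/TRAP/FLEX.

    ``gains[k-1]`` holds the order-``k`` smoothed gain; ``operators`` the
    matching patch profiles (``None`` means order-1 indicator profiles).
    Ties in the (order, center) argmax break toward the lowest order, then the
    lowest dipole index — the sparsest explanation wins.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (q, t)")
    if not np.any(data):
        raise ValueError("data is all zero")
    q = data.shape[0]

    c = data_covariance(data)
    base = decompose(c, epsilon)
    n0 = base.signal_rank
    if max_iter is None:
        # loop bound i < q; in practice the threshold or subspace
        # exhaustion stops the recursion much earlier
        max_iter = q
    total_power = float(np.trace(c))

    cands: list[Candidate] = []
    b = np.empty((q, 0))
    s_diag = np.zeros(n_dipoles)
    peaks: list[float] = []
    stop = STOP_MAX_ITER

    i = 0
    while i < max_iter:
        qi = out_projector(b)
        ci = qi @ c @ qi
        if np.trace(ci) <= 1e-12 * max(total_power, 1e-300):
            stop = STOP_RANK_EXHAUSTED
            break
        vals, vecs = np.linalg.eigh(0.5 * (ci + ci.T))
        vals = np.clip(vals[::-1], 0.0, None)
        vecs = vecs[:, ::-1]
        try:
            ni = select_signal_rank(vals, epsilon)
        except ValueError:
            stop = STOP_RANK_EXHAUSTED
            break
        rank = (n0 - i) if truncate else ni
        rank = min(rank, int(np.sum(vals > 1e-12 * vals[0])))
        if rank < 1:
            stop = STOP_RANK_EXHAUSTED
            break
        p_i = signal_projector(vecs, rank)

        best = None  # (score, order, center)
        for k, g in enumerate(gains, start=1):
            mu = localizer(p_i, qi, g)
            j = int(np.argmax(mu))  # np.argmax already takes the lowest index
            if best is None or mu[j] > best[0] + 1e-12:
                best = (float(mu[j]), k, j)
        peak, k_hat, p_hat = best
        peaks.append(peak)
        if peak < threshold:
            stop = STOP_BELOW_THRESHOLD
            break

        topo = gains[k_hat - 1][:, p_hat].copy()
        if operators is None or k_hat == 1:
            weights = np.zeros(n_dipoles)
            weights[p_hat] = 1.0
        else:
            weights = operators[k_hat - 1][:, p_hat].copy()
        cands.append(
            Candidate(
                center_index=p_hat,
                order=k_hat,
                topography=topo,
                patch_weights=weights,
                peak_score=peak,
            )
        )
        b = np.column_stack([b, topo])
        s_diag = s_diag + weights
        i += 1

    return CandidateSet(
        candidates=cands,
        topographies=b,
        out_projector=out_projector(b),
        source_cov_diag=s_diag,
        stop_reason=stop,
        peak_history=peaks,
    )


def trap_music(
    data: np.ndarray,
    lead: LeadField,
    threshold: float = DEFAULT_THRESHOLD,
    truncate: bool = True,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int | None = None,
) -> CandidateSet:
    """TRAP-MUSIC (``truncate=True``) or RAP-MUSIC (``truncate=False``) scan.

    Single-dipole candidates only; each recursion out-projects the selected
    topographies, re-decomposes the projected covariance, and picks the dipole
    maximizing ``‖P Q l‖²/‖Q l‖²``.  With truncation, recursion ``i`` keeps
    ``ñ − i`` leading components of the projected subspace (one dimension
    removed per found source), with ``ñ`` the initial signal rank.
    """
    return _recursive_scan(
        data,
        [lead.gain],
        None,
        lead.n_dipoles,
        threshold,
        epsilon,
        max_iter,
        truncate,
    )


def rap_music(
    data: np.ndarray,
    lead: LeadField,
    threshold: float = DEFAULT_THRESHOLD,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int | None = None,
) -> CandidateSet:
    """RAP-MUSIC: the recursive scan without subspace truncation."""
    return trap_music(
        data, lead, threshold=threshold, truncate=False, epsilon=epsilon,
        max_iter=max_iter,
    )


def flex_music(
    data: np.ndarray,
    dictionary: SmoothnessDictionary,
    threshold: float = DEFAULT_THRESHOLD,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int | None = None,
) -> CandidateSet:
    """FLEX-MUSIC scan over the joint (smoothness order, center) candidate set.

    At each recursion the localizer is evaluated for every smoothed gain
    ``L_k`` and every center; the global argmax fixes both the estimated
    extent ``k̂`` and the center ``p̂``.  The selected patch profile (column of
    ``G_k̂``) is accumulated into the diagonal source covariance.  No subspace
    truncation is applied.  With ``max_order == 1`` this reduces exactly to
    RAP-MUSIC.
    """
    n_dipoles = dictionary.smoothed_gains[0].shape[1]
    return _recursive_scan(
        data,
        dictionary.smoothed_gains,
        dictionary.operators,
        n_dipoles,
        threshold,
        epsilon,
        max_iter,
        truncate=False,
    )


def wmne_reconstruct(
    source_cov: np.ndarray,
    lead: LeadField,
    data: np.ndarray,
    ridge: float = DEFAULT_RIDGE,
) -> SourceEstimate:
    """Weighted minimum-norm currents ``Ĵ = S Lᵀ (L S Lᵀ + λ I)⁻¹ M``.

    ``source_cov`` may be the p×p matrix S or just its length-p diagonal.
    The ridge is relative: the absolute Tikhonov term is
    ``ridge · trace(L S Lᵀ)/q``.  Rows outside the support of S are exactly
    zero.  Falls back to a pseudoinverse if the regularized system is
    singular.
    """
    s = np.asarray(source_cov, dtype=float)
    s_diag = np.diag(s) if s.ndim == 2 else s
    if np.any(s_diag < -1e-12):
        raise ValueError("source covariance diagonal must be nonnegative")
    data = np.asarray(data, dtype=float)
    l = lead.gain
    q, p = l.shape
    if s_diag.shape[0] != p or data.shape[0] != q:
        raise ValueError("dimension mismatch between source_cov, lead and data")

    if not np.any(s_diag > 0):
        warnings.warn("source covariance is all zero; returning zero estimate",
                      stacklevel=2)
        zero = np.zeros((p, data.shape[1]))
        return SourceEstimate(currents=zero, candidate_set=None)

    lw = l * s_diag[None, :]  # L S
    gram = lw @ l.T  # L S Lᵀ
    lam = ridge * np.trace(gram) / q
    try:
        x = np.linalg.solve(gram + lam * np.eye(q), data)
    except np.linalg.LinAlgError:
        x = np.linalg.pinv(gram + lam * np.eye(q)) @ data
    currents = lw.T @ x  # S Lᵀ x — zero rows off-support by construction
    return SourceEstimate(currents=currents, candidate_set=None)


SOLVER_NAMES = ("music", "rap", "trap", "flex")


def apply_solver(
    name: str,
    data: np.ndarray,
    lead: LeadField,
    dictionary: SmoothnessDictionary | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int | None = None,
    ridge: float = DEFAULT_RIDGE,
    criterion: float = 0.95,
) -> tuple[SourceEstimate, CandidateSet | None]:
    """Uniform solver front end: (data, forward model, config) → estimate.

    ``name`` is one of ``"music"``, ``"rap"``, ``"trap"``, ``"flex"``.  The
    recursive solvers return their candidate set alongside the weighted
    minimum-norm reconstruction; one-shot MUSIC reconstructs from the
    above-criterion mask.
    """
    if name not in SOLVER_NAMES:
        raise ValueError(f"unknown solver {name!r}; choose from {SOLVER_NAMES}")
    if name == "flex":
        if dictionary is None:
            raise ValueError("flex solver requires a smoothness dictionary")
        cset = flex_music(data, dictionary, threshold, epsilon, max_iter)
    elif name == "trap":
        cset = trap_music(data, lead, threshold, True, epsilon, max_iter)
    elif name == "rap":
        cset = rap_music(data, lead, threshold, epsilon, max_iter)
    else:  # one-shot MUSIC
        mu, mask = music_oneshot(data, lead, criterion, epsilon)
        s_diag = mask.astype(float)
        if not mask.any():
            est = SourceEstimate(
                currents=np.zeros((lead.n_dipoles, data.shape[1])),
                candidate_set=None,
            )
            return est, None
        est = wmne_reconstruct(s_diag, lead, data, ridge)
        return est, None

    if len(cset) == 0:
        est = SourceEstimate(
            currents=np.zeros((lead.n_dipoles, np.asarray(data).shape[1])),
            candidate_set=cset,
        )
        return est, cset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = wmne_reconstruct(cset.source_cov_diag, lead, data, ridge)
    est.candidate_set = cset
    return est, cset


def save_estimate(prefix, estimate: SourceEstimate) -> None:
    """Serialize currents to ``<prefix>.npz`` + JSON sidecar with provenance."""
    np.savez_compressed(f"{prefix}.npz", currents=estimate.currents)
    meta = {"candidates": [], "stop_reason": None}
    cset = estimate.candidate_set
    if cset is not None:
        meta["stop_reason"] = cset.stop_reason
        meta["candidates"] = [
            {
                "center_index": int(c.center_index),
                "order": int(c.order),
                "peak_score": float(c.peak_score),
            }
            for c in cset.candidates
        ]
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_estimate(prefix) -> tuple[np.ndarray, dict]:
    with np.load(f"{prefix}.npz") as f:
        currents = f["currents"]
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    return currents, meta
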