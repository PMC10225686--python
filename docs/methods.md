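# Methods

This note documents the models, conventions and numerical choices behind
`flexmusic`, and what the synthetic benchmark does and does not show.

## Forward model and subspace machinery

The sensor data follow `M = L J + ζ` with a fixed-orientation leadfield
`L ∈ ℝ^{q×p}` (µV per nAm). The sensor covariance is the raw outer product
`C = M Mᵀ` — no mean removal and no `1/t` scaling, since the localizer and
the rank rule are invariant to both (flags expose the alternatives).

**Signal-rank selection.** Eigenvalues are normalized by the largest and the
signal subspace is the leading block with `d̃_i ≥ ε`, default ε = 0.01. We
considered a gap-based variant (end the subspace at the first consecutive
drop below ε) and rejected it: whenever two sources have similar power their
neighboring eigenvalues differ by less than ε and the gap rule truncates the
subspace *inside* the signal block, which in benchmark runs collapsed
recovery of the weaker half of the sources. The threshold rule errs toward
overestimating the rank, which is the safe direction for subspace scanners:
extra noise dimensions dilute localizer contrast slightly, whereas a lost
signal dimension makes a source unrecoverable. The rank is re-selected on
every recursion's spectrum of the out-projected covariance `Q C Q`.

**Localizer.** `μ_j = ‖P Q l_j‖²/‖Q l_j‖²`. Columns with
`‖Q l_j‖² < 10⁻¹² ‖l_j‖²` score 0: they are already explained by the
selected topographies and must not be re-selected. The relative (per-column)
tolerance keeps the localizer exactly invariant to column rescaling.

## Recursive solvers

All three recursive scanners share one loop: build `Q = I − B B†` from the
selected topographies, eigendecompose `Q C Q`, form the subspace projector,
scan the localizer, and append the argmax candidate. Iteration continues
while `i < q` and stops earlier when the localizer maximum falls below the
threshold (default 0.975), or when the residual trace of `Q C Q` falls below
10⁻¹² of the original trace (subspace exhausted). The bound `i < q` matters:
out-projection re-exposes sources whose eigenvalues were initially buried,
so capping iterations at the first rank estimate leaves above-threshold
peaks unharvested.

* **RAP**: subspace rank re-selected each recursion, no truncation.
* **TRAP**: at recursion i the projected subspace is truncated to `ñ₀ − i`
  leading components, with `ñ₀` the initial rank estimate (one dimension
  removed per found source). The published truncation expression is garbled
  in the source literature; this is the standard convention.
* **FLEX**: the localizer is evaluated for every smoothed gain `L_k` and the
  argmax is joint over (k, p). Ties break toward the lowest order, then the
  lowest dipole index — prefer the sparsest explanation. No truncation.
  With `max_order = 1` the recursion is identical to RAP (tested).

**Smoothness dictionary.** Default `G_k` for k ≥ 2 is the column-normalized
`(A + I)^{k−1}` (A = mesh adjacency): every column is nonnegative, sums to
one, and is supported exactly on the radius-(k−1) graph neighborhood of its
center, so localizer values stay scale-free and patches grow monotonically
with k. A "literal" variant (`G_2` = combinatorial graph Laplacian,
`G_k = G_{k−1} A`) is available for comparison but is sign-indefinite and
grows without bound, which makes the patch profiles physically
uninterpretable; it is not used by default. Default `max_order` K = 8;
smaller source spaces warrant smaller K (a radius-7 patch on a 162-vertex
icosphere already covers a large fraction of the mesh).

**Source covariance and reconstruction.** Selecting candidate (k̂, p̂) adds
the column of `G_k̂` at p̂ onto the diagonal of the source covariance S.
Keeping S diagonal makes `L S Lᵀ` cheap and gives the weighted-MNE reading
of Ĵ = S Lᵀ (L S Lᵀ + λI)⁻¹ M with per-dipole weights; rows of Ĵ outside
the support of S are exactly zero. The ridge is relative,
λ = ridge · trace(L S Lᵀ)/q with ridge = 10⁻⁶ by default, because `L S Lᵀ`
is singular whenever rank(support) < q; a pseudoinverse fallback covers the
remaining degenerate cases. An empty candidate set yields an all-zero
estimate with a warning rather than an error: downstream metrics penalize
it explicitly.

## Synthetic benchmark

The generator emulates an evaluation protocol over a triangulated source
space: per sample, 1–10 sources, each either a single dipole (radius 0) or a
patch of graph radius 1–3; half of the samples single-dipole, half extended.
Each source gets one shared time course (the patch is coherent, hence rank
one over time) generated by spectral shaping of white noise with amplitude
`f^{−β/2}` and standardized; β uniform in [0, 2] per sample (white to
Brownian-like smoothness). Per-source peak amplitude is uniform in
[1, 10] nAm. Noise is spatio-temporally white noise mixed across channels
by a random square matrix (inducing inter-channel correlations across
[−1, 1]) and rescaled so that the amplitude ratio RMS(L J)/RMS(ζ) equals the
drawn SNR exactly.

**SNR sampling.** The SNR is drawn *uniformly* in [0.1, 100] per sample.
A log-uniform draw (available as `snr_sampling="log"`) weights the three
decades equally but places half of all samples below amplitude-SNR ≈ 3,
where no subspace method can place every one of up to ten sources exactly —
under that convention the median single-dipole localization error is
structurally nonzero for every solver, which contradicts the benchmark
behavior this protocol is designed to exhibit (median MLE of 0 for
single-dipole samples). The uniform draw is therefore the default and the
convention is recorded per sample.

**Patch profiles.** By default simulated patches use the same `G_k` columns
the solver scans (normalized to unit peak), i.e. the generator is
model-matched. This is optimistic: real cortical patches are not spherical
and not drawn from the solver's dictionary. The `patch_profile="uniform"`
option (flat indicator over the neighborhood) provides a model-mismatch
condition. Passing benchmark tests therefore demonstrates correct mechanics
and the relative ordering of solvers under matched conditions, not absolute
real-data accuracy.

The synthetic leadfield places radially oriented dipoles on a subdivided
icosahedron (radius 70 mm) and 64 virtual sensors on a concentric sphere
(×1.35), with dipole-like `(n·r̂)/d²` sensitivity plus a 2% seeded random
perturbation so no two columns are collinear. It reproduces the qualitative
geometry of an EEG montage (smooth, distance-decaying, spatially overlapping
topographies) but not volume-conduction detail; absolute EMD/MSE scales are
therefore convention- and geometry-dependent and are reported, not compared
across forward models.

## Metrics

* **MLE** (mm): local maxima of the absolute time-averaged profiles of J and
  Ĵ are found on the source graph (a maximum must also reach 10% of the
  global maximum — the floor suppresses numerical ripple from
  minimum-norm-type solutions; connected equal-valued plateaus contribute
  one representative). The error is the mean over *true* maxima of the
  distance to the nearest estimated maximum. An estimate with no maxima is
  penalized with the maximum pairwise distance of the source space — a
  bounded, monotone penalty that keeps the sample in the aggregate.
* **EMD** (mm): exact optimal transport between the two mass-normalized
  spatial profiles, solved as a linear program (HiGHS) restricted to the two
  supports, with Euclidean ground distance. Checked in tests against an
  independent min-cost-matching oracle on integer-mass instances.
* **MSE**: mean squared entrywise difference (a Frobenius-norm variant sits
  behind a flag).
* **Sparsity**: mean columnwise L1 norm after unit-L2 column scaling, in
  [1, √p]; 1 for one active dipole, √p for uniform activity. Its Pearson
  correlation between ground truth and estimate measures whether a solver
  recovers the *extent* of activity, the headline capability of the
  flexible-extent scanner.

Solver failures or undefined metrics (EMD/sparsity of an all-zero estimate)
are recorded as missing and excluded from medians; MLE still penalizes the
empty estimate.

## Problem sizes

The shipped test suite and the acceptance script run on synthetic spheres:
162 dipoles for unit/recovery tests and 642 dipoles / 200 samples for the
benchmark, sizes at which the full pipeline completes in well under a minute
while preserving the q < p regime and the mesh-graph structure the method
depends on. The full-protocol driver (`replicate-full`) runs the
1000-sample benchmark on a user-supplied 64-channel / 1284-dipole template
forward model.

## Known limitations

* Extent is modelled as graph-radius patches from the dictionary; elliptical
  or irregular sources are only approximated by unions of spherical patches.
* No pre-whitening: colored sensor noise is assumed to be handled upstream.
* Free-orientation (3-component) dipoles are out of scope; the forward model
  must be fixed-orientation.
* The one-shot MUSIC solver reconstructs from a thresholded localizer mask
  and is included as a baseline, not a recommended estimator.
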