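# flexmusic

Recursive subspace source localization for EEG/MEG with flexible
source-extent estimation.

## The problem

M/EEG measures neural activity at the scalp with millisecond resolution, but
recovering *where* in the brain that activity originates is an ill-posed
inverse problem: the sensor data `M ∈ ℝ^{q×t}` (q channels, t time points)
relates to the unknown cortical currents `J ∈ ℝ^{p×t}` (p dipoles with fixed
orientation perpendicular to the cortex) through the leadfield
`M = L J + ζ`, with `L ∈ ℝ^{q×p}` and noise ζ, and p ≫ q.

MUSIC-family scanners attack this by splitting the sensor covariance
`C = M Mᵀ = U D Uᵀ` into a signal subspace (leading eigenvectors,
`P_s = U_s U_sᵀ`) and a noise subspace, then scoring every candidate source
topography `l` by how well it lies inside the signal subspace,

```
μ = ‖P Q l‖² / ‖Q l‖²  ∈ [0, 1],
```

where `Q = I − B B†` out-projects the topographies `B` of sources already
found, so each recursion explains a new part of the subspace
(RAP-MUSIC). TRAP-MUSIC additionally truncates the retained subspace by one
dimension per found source to suppress residual leakage (the "RAP dilemma").

These scanners only look for point dipoles, yet cortical activity is often
spatially coherent over patches. **FLEX-MUSIC** widens the candidate set: a
dictionary of smoothing operators `G_k` (with `G_1 = I`) turns the leadfield
into progressively smoother versions `L_k = L G_k`, where the column of
`G_k` at dipole c is a nonnegative weight profile over the dipoles within
graph radius k−1 of c on the cortical mesh. Each recursion takes the argmax
of μ jointly over (order k, center p), so both the location *and* the extent
of each source are estimated; the selected patch profiles accumulate into a
diagonal source covariance `S` and the final currents are the weighted
minimum-norm estimate

```
Ĵ = S Lᵀ (L S Lᵀ + λI)⁻¹ M .
```

The package provides the FLEX/TRAP/RAP/one-shot-MUSIC solvers, a synthetic
benchmark (single dipoles and patches with 1/f^β time courses, channel-
correlated noise at controlled SNR), and the evaluation metrics (mean
localization error, earth mover's distance, MSE, and the L1-of-L2-normalized
sparsity measure), for researchers comparing extent-aware inverse solvers.

## Worked example

```python
import flexmusic as fm

# synthetic 64-channel / 162-dipole spherical forward model
space, lead = fm.synthesize_source_space(subdivisions=2, radius_mm=70, seed=0)
dictionary = fm.build_smoothness_dictionary(lead, space, max_order=8)

# one simulated sample: two patch sources (radii 1 and 2), amplitude SNR 20
cfg = fm.SimulationConfig(n_samples=1, n_sources_range=(2, 2),
                          extent_orders=(1, 2), snr_range=(20, 20), seed=7)
sample = fm.generate_dataset(space, lead, dictionary, cfg)[0]
print("true centers:", sample.true_centers, "radii:", sample.true_orders)

cset = fm.flex_music(sample.sensor_data, dictionary)
for c in cset.candidates:
    print(f"found dipole {c.center_index} at order {c.order} "
          f"(radius {c.order - 1}), score {c.peak_score:.4f}")

est = fm.wmne_reconstruct(cset.source_cov_diag, lead, sample.sensor_data)
print("MLE  %.2f mm" % fm.mean_localization_error(
    sample.currents, est.currents, space))
```

prints

```
true centers: [152, 101] radii: [2, 1]
found dipole 101 at order 2 (radius 1), score 0.9998
found dipole 152 at order 3 (radius 2), score 0.9992
MLE  20.94 mm
```

Both centers and both extents are recovered exactly (dictionary order k
corresponds to radius k−1). The localizer scores near 1 say each selected
patch topography lies almost entirely inside the remaining signal subspace.
The nonzero MLE reflects that at this coarse 162-dipole resolution
(≈18 mm vertex spacing) the spatial maximum of the weighted-MNE current map
of a patch can sit one mesh vertex away from the patch center; at finer
resolutions this error shrinks toward zero.

## Benchmark CLI

```
flexmusic run --seed 1 --n-samples 100 --out bench/      # simulate+solve+score
flexmusic simulate --n-samples 100 --out bench/          # dataset only
flexmusic evaluate bench/dataset --solver flex --solver trap
flexmusic replicate-full <forward.npz>                   # full 1000-sample protocol
```

`replicate-full` expects a precomputed 64-channel / 1284-dipole template-brain
forward solution (e.g. fsaverage with icosahedral source spacing), which must
be obtained separately; `flexmusic.load_forward_mne` converts an MNE `.fif`
forward into the package's `.npz` container.

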