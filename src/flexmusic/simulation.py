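"""Synthetic ground-truth generator for the benchmark.

Emulates the evaluation protocol: each sample draws between 1 and 10 sources,
either single dipoles or spherical patches of graph radius 1–3, gives every
source one shared 1/f^β time course (coherent activity over the patch), and
projects through the leadfield with channel-correlated white noise scaled to
a randomly drawn signal-to-noise ratio.

Conventions that the protocol leaves open, fixed here and recorded in every
sample's metadata: SNR is the amplitude ratio RMS(L J)/RMS(ζ) drawn
uniformly in [0.1, 100]; the spectral exponent β is uniform in [0, 2] per
sample; per-source peak amplitudes are uniform in [1, 10] nAm.  Extent is
expressed as graph radius: radius 0 is a single dipole, radius r ≥ 1 maps to
dictionary order k = r + 1.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict

import numpy as np

from .source_space import LeadField, SmoothnessDictionary, SourceSpace

__all__ = [
    "SimulationConfig",
    "SimulatedSample",
    "colored_time_course",
    "sample_sources",
    "add_noise",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "export_metadata_csv",
]


@dataclass
class SimulationConfig:
    """Benchmark simulation conditions.

    ``extent_orders`` are graph radii: 0 means single dipoles; when both 0 and
    positive radii are present, half of the samples are single-dipole and the
    other half extended.
    """

    n_samples: int = 1000
    n_sources_range: tuple[int, int] = (1, 10)
    extent_orders: tuple[int, ...] = (0, 1, 2, 3)
    n_timepoints: int = 20
    snr_range: tuple[float, float] = (0.1, 100.0)
    beta_range: tuple[float, float] = (0.0, 2.0)
    amplitude_range_nAm: tuple[float, float] = (1.0, 10.0)
    seed: int = 0
    patch_profile: str = "dictionary"  # or "uniform" (model-mismatch mode)
    snr_mode: str = "amplitude"  # or "power"
    snr_sampling: str = "uniform"  # or "log"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.extent_orders:
            raise ValueError("extent_orders must be nonempty")
        if self.n_sources_range[0] < 1 or self.n_sources_range[1] < self.n_sources_range[0]:
            raise ValueError("invalid n_sources_range")
        if self.snr_range[0] <= 0 or self.snr_range[1] < self.snr_range[0]:
            raise ValueError("snr_range must be positive and nonempty")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.patch_profile not in ("dictionary", "uniform"):
            raise ValueError("patch_profile must be 'dictionary' or 'uniform'")
        if self.snr_mode not in ("amplitude", "power"):
            raise ValueError("snr_mode must be 'amplitude' or 'power'")
        if self.snr_sampling not in ("uniform", "log"):
            raise ValueError("snr_sampling must be 'uniform' or 'log'")


@dataclass
class SimulatedSample:
    """One ground-truth/EEG pair: ``sensor_data = L @ currents + noise``."""

    currents: np.ndarray  # (p, t) ground truth J, nAm
    sensor_data: np.ndarray  # (q, t) M, µV
    noise: np.ndarray  # (q, t) ζ
    true_centers: list[int]
    true_orders: list[int]  # graph radii; 0 = single dipole
    snr: float
    beta: float
    extended: bool = False
    sample_id: int = 0


def colored_time_course(n_timepoints: int, beta: float, rng) -> np.ndarray:
    """A 1/f^β waveform: spectrally shaped white noise, standardized.

    White noise is transformed to the frequency domain, each positive
    frequency ``f`` is scaled by ``f^(−β/2)`` (so the power spectrum follows
    ``1/f^β``), and the inverse transform is standardized to zero mean and
    unit variance.  ``beta = 0`` reproduces white noise.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    white = rng.standard_normal(n_timepoints)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_timepoints)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shape, n=n_timepoints)
    x = x - x.mean()
    sd = x.std()
    if sd == 0:  # pathological draw; retry deterministically
        return colored_time_course(n_timepoints, beta, rng)
    return x / sd


def _patch_profile(
    space: SourceSpace,
    dictionary: SmoothnessDictionary,
    center: int,
    radius: int,
    mode: str,
) -> np.ndarray:
    """Spatial weight profile of one source (unit peak amplitude)."""
    p = space.n_dipoles
    if radius == 0:
        w = np.zeros(p)
        w[center] = 1.0
        return w
    order = radius + 1
    if order > dictionary.max_order:
        raise ValueError(
            f"extent radius {radius} needs dictionary order {order} "
            f"but max_order is {dictionary.max_order}"
        )
    col = dictionary.operator(order)[:, center].copy()
    if mode == "uniform":
        col = (col > 0).astype(float)
    return col / col.max()


def sample_sources(
    space: SourceSpace,
    dictionary: SmoothnessDictionary,
    config: SimulationConfig,
    rng,
    extent_orders: tuple[int, ...] | None = None,
) -> tuple[np.ndarray, list[int], list[int], float]:
    """Draw one sample's ground-truth currents.

    Returns ``(J, centers, radii, beta)``.  Each source gets an independent
    time course shared coherently across its whole patch, so every source is
    rank one over time.  Centers are drawn without replacement (collisions
    resampled).
    """
    orders = extent_orders if extent_orders is not None else config.extent_orders
    lo, hi = config.n_sources_range
    n_sources = int(rng.integers(lo, hi + 1))
    centers = rng.choice(space.n_dipoles, size=n_sources, replace=False)
    beta = float(rng.uniform(*config.beta_range))
    j = np.zeros((space.n_dipoles, config.n_timepoints))
    radii = []
    for c in centers:
        r = int(rng.choice(orders))
        radii.append(r)
        amp = float(rng.uniform(*config.amplitude_range_nAm))
        profile = _patch_profile(space, dictionary, int(c), r, config.patch_profile)
        tc = colored_time_course(config.n_timepoints, beta, rng)
        j += amp * profile[:, None] * tc[None, :]
    return j, [int(c) for c in centers], radii, beta


def add_noise(
    clean: np.ndarray, snr: float, rng, mode: str = "amplitude"
) -> tuple[np.ndarray, np.ndarray]:
    """Add channel-correlated white noise at a controlled SNR.

    The noise is spatio-temporally white noise mixed across channels by a
    seeded random square matrix, which induces pairwise channel correlations
    spanning the full [-1, 1] range, then rescaled so that
    ``RMS(clean)/RMS(noise) = snr`` (amplitude mode) or the power ratio
    equals ``snr`` (power mode).  Returns ``(noisy, noise)``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    clean = np.asarray(clean, dtype=float)
    if not np.any(clean):
        raise ValueError("clean signal is all zero; SNR undefined")
    q, t = clean.shape
    mixing = rng.standard_normal((q, q)) / np.sqrt(q)
    noise = mixing @ rng.standard_normal((q, t))
    rms_clean = np.sqrt(np.mean(clean**2))
    rms_noise = np.sqrt(np.mean(noise**2))
    target = snr if mode == "amplitude" else np.sqrt(snr)
    noise *= rms_clean / (target * rms_noise)
    return clean + noise, noise


def generate_dataset(
    space: SourceSpace,
    lead: LeadField,
    dictionary: SmoothnessDictionary,
    config: SimulationConfig,
) -> list[SimulatedSample]:
    """Simulate the full benchmark dataset; deterministic given ``config.seed``.

    When ``extent_orders`` mixes radius 0 with positive radii, the first
    ``ceil(n/2)`` samples are single-dipole and the rest extended.  SNR is
    drawn uniformly over ``snr_range`` by default ("a random SNR within the
    given range"); ``snr_sampling="log"`` draws log-uniformly instead, which
    weights the three decades of the range equally but concentrates most
    samples at SNRs where no subspace method can recover every source.
    """
    rng = np.random.default_rng(config.seed)
    singles = tuple(r for r in config.extent_orders if r == 0)
    extended = tuple(r for r in config.extent_orders if r > 0)
    mixed = bool(singles) and bool(extended)
    n_single = (config.n_samples + 1) // 2 if mixed else (
        config.n_samples if singles and not extended else 0
    )

    log_lo, log_hi = np.log10(config.snr_range[0]), np.log10(config.snr_range[1])
    samples = []
    for idx in range(config.n_samples):
        if mixed:
            orders = singles if idx < n_single else extended
        else:
            orders = config.extent_orders
        j, centers, radii, beta = sample_sources(
            space, dictionary, config, rng, extent_orders=orders
        )
        clean = lead.gain @ j
        if config.snr_sampling == "log":
            snr = float(10.0 ** rng.uniform(log_lo, log_hi))
        else:
            snr = float(rng.uniform(*config.snr_range))
        noisy, noise = add_noise(clean, snr, rng, mode=config.snr_mode)
        samples.append(
            SimulatedSample(
                currents=j,
                sensor_data=noisy,
                noise=noise,
                true_centers=centers,
                true_orders=radii,
                snr=snr,
                beta=beta,
                extended=any(r > 0 for r in radii),
                sample_id=idx,
            )
        )
    return samples


def save_dataset(prefix, samples: list[SimulatedSample],
                 config: SimulationConfig | None = None) -> None:
    """One .npz array container per dataset plus a JSON manifest."""
    arrays = {}
    for s in samples:
        arrays[f"currents_{s.sample_id}"] = s.currents
        arrays[f"sensor_{s.sample_id}"] = s.sensor_data
        arrays[f"noise_{s.sample_id}"] = s.noise
    np.savez_compressed(f"{prefix}.npz", **arrays)
    manifest = {
        "config": asdict(config) if config is not None else None,
        "samples": [
            {
                "sample_id": s.sample_id,
                "true_centers": s.true_centers,
                "true_orders": s.true_orders,
                "snr": s.snr,
                "beta": s.beta,
                "extended": s.extended,
            }
            for s in samples
        ],
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_dataset(prefix) -> list[SimulatedSample]:
    with open(f"{prefix}.json") as fh:
        manifest = json.load(fh)
    samples = []
    with np.load(f"{prefix}.npz") as f:
        for meta in manifest["samples"]:
            sid = meta["sample_id"]
            samples.append(
                SimulatedSample(
                    currents=f[f"currents_{sid}"],
                    sensor_data=f[f"sensor_{sid}"],
                    noise=f[f"noise_{sid}"],
                    true_centers=meta["true_centers"],
                    true_orders=meta["true_orders"],
                    snr=meta["snr"],
                    beta=meta["beta"],
                    extended=meta["extended"],
                    sample_id=sid,
                )
            )
    return samples


def export_metadata_csv(path, samples: list[SimulatedSample]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "n_sources", "true_centers", "true_orders",
                    "snr", "beta", "extended"])
        for s in samples:
            w.writerow([
                s.sample_id, len(s.true_centers),
                ";".join(map(str, s.true_centers)),
                ";".join(map(str, s.true_orders)),
                s.snr, s.beta, s.extended,
            ])
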