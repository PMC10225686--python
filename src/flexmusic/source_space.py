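"""Discretized cortical source model: dipole positions, mesh adjacency, and the
smoothness-operator dictionary used for flexible-extent source scanning.

The source space is a graph: vertices are dipole locations (fixed orientation,
perpendicular to the cortical surface) and edges connect dipoles that share a
mesh triangle.  The smoothness dictionary turns the leadfield ``L`` into a
family of progressively smoothed leadfields ``L_k = L @ G_k`` where the column
of ``G_k`` at dipole ``c`` is a nonnegative weight profile supported on the
dipoles within graph distance ``k - 1`` of ``c``.  ``G_1`` is the identity, so
single dipoles always remain part of the candidate set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "SourceSpace",
    "LeadField",
    "SmoothnessDictionary",
    "build_adjacency",
    "build_smoothness_dictionary",
    "synthesize_source_space",
    "save_forward_npz",
    "load_forward_npz",
    "save_forward_text",
    "load_forward_text",
    "load_forward_mne",
]


@dataclass
class SourceSpace:
    """Dipole positions (mm) plus the binary neighborhood structure of the mesh.

    Parameters
    ----------
    positions : (p, 3) float array
        Dipole coordinates in millimetres.
    adjacency : (p, p) array
        Symmetric binary neighbor indicator with zero diagonal.
    """

    positions: np.ndarray
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.adjacency = np.asarray(self.adjacency)
        p = self.positions.shape[0]
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (p, 3)")
        if self.adjacency.shape != (p, p):
            raise ValueError("adjacency must have shape (p, p)")
        a = self.adjacency
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal")
        vals = np.unique(a)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("adjacency entries must be 0 or 1")
        n_comp, _ = connected_components(sp.csr_matrix(a), directed=False)
        if n_comp > 1:
            warnings.warn(
                f"source space graph is not connected ({n_comp} components)",
                stacklevel=2,
            )

    @property
    def n_dipoles(self) -> int:
        return self.positions.shape[0]

    def graph_distances(self) -> np.ndarray:
        """All-pairs unweighted graph distance (hops); inf across components."""
        return shortest_path(sp.csr_matrix(self.adjacency), unweighted=True)

    def max_pairwise_distance(self) -> float:
        """Largest Euclidean distance (mm) between any two dipoles."""
        from scipy.spatial.distance import pdist

        if self.n_dipoles < 2:
            return 0.0
        return float(pdist(self.positions).max())


@dataclass
class LeadField:
    """Gain matrix mapping dipole currents (nAm) to sensor readings (µV).

    ``gain`` has shape (q channels, p dipoles).
    """

    gain: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise ValueError("gain must be a 2-D (q, p) matrix")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain contains non-finite entries")
        if self.gain.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        col_norms = np.linalg.norm(self.gain, axis=0)
        if np.any(col_norms == 0):
            raise ValueError("gain has an all-zero column; localizer undefined")
        if not self.channel_names:
            self.channel_names = [f"EEG{i:03d}" for i in range(self.gain.shape[0])]
        if len(self.channel_names) != self.gain.shape[0]:
            raise ValueError("channel_names length must match number of rows")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.gain.shape[1]


@dataclass
class SmoothnessDictionary:
    """Family of smoothing operators ``G_k`` and smoothed gains ``L_k = L G_k``.

    Order ``k`` covers graph radius ``k - 1``: ``G_1`` is the identity (single
    dipoles) and the column of ``G_k`` at dipole ``c`` is supported on the
    dipoles within ``k - 1`` hops of ``c``.
    """

    operators: list[np.ndarray]
    smoothed_gains: list[np.ndarray]

    @property
    def max_order(self) -> int:
        return len(self.operators)

    def operator(self, order: int) -> np.ndarray:
        """1-based access: ``operator(1)`` is the identity."""
        return self.operators[order - 1]

    def smoothed_gain(self, order: int) -> np.ndarray:
        return self.smoothed_gains[order - 1]


def build_adjacency(triangles, n_vertices: int) -> np.ndarray:
    """Binary vertex adjacency from a triangle list.

    Two vertices are adjacent iff they co-occur in at least one triangle.
    """
    triangles = np.asarray(triangles, dtype=int).reshape(-1, 3)
    if triangles.size and (triangles.min() < 0 or triangles.max() >= n_vertices):
        raise ValueError("triangle vertex index out of range")
    a = np.zeros((n_vertices, n_vertices), dtype=np.int8)
    for i, j, k in triangles:
        for u, v in ((i, j), (i, k), (j, k)):
            if u != v:
                a[u, v] = 1
                a[v, u] = 1
    return a


def build_smoothness_dictionary(
    lead: LeadField,
    space: SourceSpace,
    max_order: int = 8,
    variant: str = "normalized",
) -> SmoothnessDictionary:
    """Build the smoothed-leadfield dictionary up to ``max_order``.

    Parameters
    ----------
    variant
        ``"normalized"`` (default): ``G_k`` for ``k >= 2`` is the
        column-normalized ``(A + I)^(k-1)`` — every column is nonnegative,
        sums to one, and is supported exactly on the radius-``k-1``
        neighborhood of its center.  ``"literal"``: ``G_2`` is the
        combinatorial graph Laplacian and ``G_k = G_{k-1} A`` for ``k > 2``
        (unnormalized, sign-indefinite); provided for comparison only.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    p = space.n_dipoles
    if lead.n_dipoles != p:
        raise ValueError(
            f"leadfield has {lead.n_dipoles} dipoles but source space has {p}"
        )
    if variant not in ("normalized", "literal"):
        raise ValueError(f"unknown variant {variant!r}")

    a = space.adjacency.astype(float)
    operators: list[np.ndarray] = [np.eye(p)]
    if variant == "normalized":
        walk = a + np.eye(p)
        power = np.eye(p)
        for _ in range(1, max_order):
            power = power @ walk
            g = power / power.sum(axis=0, keepdims=True)
            operators.append(g)
    else:
        lap = np.diag(a.sum(axis=1)) - a
        for k in range(1, max_order):
            operators.append(lap.copy() if k == 1 else operators[-1] @ a)

    smoothed = [lead.gain @ g for g in operators]
    return SmoothnessDictionary(operators=operators, smoothed_gains=smoothed)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere point layout (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def synthesize_source_space(
    subdivisions: int = 2,
    radius_mm: float = 70.0,
    seed: int = 0,
    n_sensors: int = 64,
    sensor_radius_factor: float = 1.35,
    perturbation: float = 0.02,
) -> tuple[SourceSpace, LeadField]:
    """Synthetic spherical source space plus a geometrically plausible leadfield.

    The mesh is a recursively subdivided icosahedron (``10 * 4**s + 2``
    vertices) scaled to ``radius_mm``.  Dipoles are radially oriented;
    ``n_sensors`` virtual electrodes sit on a concentric outer sphere and each
    dipole's sensitivity falls off with distance like a current dipole
    (``(n · r̂) / d²``), plus a small seeded random perturbation so that no two
    columns are exactly collinear.  Deterministic given ``seed``.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(mesh.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    adjacency = build_adjacency(np.asarray(mesh.faces), len(verts))
    space = SourceSpace(positions=verts * radius_mm, adjacency=adjacency)

    sensors = _fibonacci_sphere(n_sensors) * (sensor_radius_factor * radius_mm)
    diff = sensors[:, None, :] - space.positions[None, :, :]  # (q, p, 3)
    dist = np.linalg.norm(diff, axis=2)
    # radial orientation: unit outward normal at each dipole
    normals = verts
    gain = np.einsum("qpd,pd->qp", diff, normals) / dist**3
    gain *= radius_mm**2  # scale-free rescale to O(1) entries

    rng = np.random.default_rng(seed)
    gain = gain + perturbation * np.sqrt(np.mean(gain**2)) * rng.standard_normal(
        gain.shape
    )
    lead = LeadField(gain=gain)
    return space, lead


# ---------------------------------------------------------------------------
# Forward-model I/O
# ---------------------------------------------------------------------------

def save_forward_npz(path, space: SourceSpace, lead: LeadField) -> None:
    """Save positions, adjacency (triplet edge list) and gain to one .npz."""
    edges = np.argwhere(np.triu(space.adjacency) > 0)
    np.savez_compressed(
        path,
        positions=space.positions,
        edges=edges,
        n_dipoles=space.n_dipoles,
        gain=lead.gain,
        channel_names=np.array(lead.channel_names),
    )


def load_forward_npz(path) -> tuple[SourceSpace, LeadField]:
    with np.load(path, allow_pickle=False) as f:
        p = int(f["n_dipoles"])
        a = np.zeros((p, p), dtype=np.int8)
        edges = f["edges"]
        a[edges[:, 0], edges[:, 1]] = 1
        a[edges[:, 1], edges[:, 0]] = 1
        space = SourceSpace(positions=f["positions"], adjacency=a)
        lead = LeadField(gain=f["gain"], channel_names=list(f["channel_names"]))
    return space, lead


def save_forward_text(prefix, space: SourceSpace, lead: LeadField) -> None:
    """Save the forward model as three delimited text files.

    ``<prefix>_positions.tsv`` (p rows, x y z in mm), ``<prefix>_edges.tsv``
    (first line ``p``, then one ``i j`` edge per line), ``<prefix>_gain.tsv``.
    """
    np.savetxt(f"{prefix}_positions.tsv", space.positions, delimiter="\t")
    edges = np.argwhere(np.triu(space.adjacency) > 0)
    with open(f"{prefix}_edges.tsv", "w") as fh:
        fh.write(f"{space.n_dipoles}\n")
        for i, j in edges:
            fh.write(f"{i}\t{j}\n")
    np.savetxt(f"{prefix}_gain.tsv", lead.gain, delimiter="\t")


def load_forward_text(prefix) -> tuple[SourceSpace, LeadField]:
    positions = np.loadtxt(f"{prefix}_positions.tsv", delimiter="\t", ndmin=2)
    with open(f"{prefix}_edges.tsv") as fh:
        p = int(fh.readline())
        a = np.zeros((p, p), dtype=np.int8)
        for line in fh:
            i, j = (int(x) for x in line.split())
            a[i, j] = 1
            a[j, i] = 1
    gain = np.loadtxt(f"{prefix}_gain.tsv", delimiter="\t", ndmin=2)
    return SourceSpace(positions=positions, adjacency=a), LeadField(gain=gain)


def load_forward_mne(fwd_path) -> tuple[SourceSpace, LeadField]:
    """Load a fixed-orientation forward solution from an MNE-Python .fif file.

    Requires the optional ``mne`` dependency.  Free-orientation forwards are
    converted to fixed (surface-normal) orientation; positions are converted
    to millimetres and adjacency is rebuilt from the source-space triangles
    restricted to the dipoles actually in use.
    """
    import mne

    fwd = mne.read_forward_solution(fwd_path, verbose="error")
    fwd = mne.convert_forward_solution(
        fwd, surf_ori=True, force_fixed=True, use_cps=True, verbose="error"
    )
    gain = fwd["sol"]["data"]
    ch_names = list(fwd["info"]["ch_names"])

    positions = []
    tri_edges = []
    offset = 0
    for src in fwd["src"]:
        vertno = src["vertno"]
        positions.append(src["rr"][vertno] * 1000.0)  # m -> mm
        remap = {v: offset + i for i, v in enumerate(vertno)}
        tris = src.get("use_tris")
        if tris is None or len(tris) == 0:
            tris = src["tris"]
        use = np.isin(tris, vertno).all(axis=1)
        for tri in np.asarray(tris)[use]:
            a, b, c = (remap[v] for v in tri)
            tri_edges.extend([(a, b), (a, c), (b, c)])
        offset += len(vertno)
    positions = np.vstack(positions)
    p = len(positions)
    adj = np.zeros((p, p), dtype=np.int8)
    for i, j in tri_edges:
        adj[i, j] = 1
        adj[j, i] = 1
    space = SourceSpace(positions=positions, adjacency=adj)
    return space, LeadField(gain=gain, channel_names=ch_names)
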