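"""Structural connectivity from a fluorescence-type culture image.

The image is partitioned into patches matching the electrode lattice.
Line segments approximating neurites are detected per patch; a Von Mises
mixture is fitted to the segment endpoints (mean = endpoint bearing on the
circle circumscribing the patch, concentration inversely proportional to
the endpoint's distance from the patch boundary, mixture weights from the
Hough votes) and discretized into an 8-bin probability histogram over the
neighbor directions.  The histograms define a weighted lattice adjacency
whose graph heat kernel, restricted to electrodes that actually hold
neurons and max-normalized, is the structural connectivity map.  Shortest
paths on the thresholded map give the structural distance between any two
electrodes in micrometres.

Direction convention: bins are ordered E, NE, N, NW, W, SW, S, SE; angles
are measured counterclockwise from the +x image axis (so "N" points toward
decreasing row index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import eigh, expm
from scipy.sparse.csgraph import dijkstra
from scipy.stats import vonmises
from skimage.draw import line as draw_line
from skimage.feature import canny
from skimage.transform import probabilistic_hough_line

from .config import HoughConfig
from .errors import ContractError, DimensionError

# bin k covers bearings within +-22.5 deg of k * 45 deg
DIRECTION_NAMES = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")
# (drow, dcol) lattice step for each direction; N = decreasing row
DIRECTION_STEPS = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)
N_DIRECTIONS = 8


@dataclass(frozen=True)
class ElectrodeGrid:
    """Regular electrode lattice with its mapping into image pixels."""

    n_rows: int = 64
    n_cols: int = 64
    pitch_um: float = 42.0
    sampling_rate_hz: float = 7000.0
    recording_length_s: float = 0.0
    offset_row_px: float = 0.0
    offset_col_px: float = 0.0
    px_per_um: float = 1.0

    def __post_init__(self):
        if self.pitch_um <= 0:
            raise ContractError("pitch must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ContractError("grid must have at least one electrode")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def patch_px(self) -> float:
        return self.pitch_um * self.px_per_um

    def node_index(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def node_rc(self, index):
        index = np.asarray(index)
        return index // self.n_cols, index % self.n_cols

    def centers_um(self, index=None):
        """Electrode-center coordinates (row_um, col_um) for node indices."""
        if index is None:
            index = np.arange(self.n_electrodes)
        r, c = self.node_rc(index)
        return np.stack([(r + 0.5) * self.pitch_um, (c + 0.5) * self.pitch_um], axis=-1)

    def euclid_um(self, idx_a, idx_b):
        ca = self.centers_um(idx_a)
        cb = self.centers_um(idx_b)
        return np.linalg.norm(ca - cb, axis=-1)

    @classmethod
    def fit_image(cls, image_shape, n_rows=64, n_cols=64, pitch_um=42.0, **kw):
        """Infer the pixel scale so the grid tiles the full image extent."""
        h, w = image_shape[:2]
        px_per_um = min(h / (n_rows * pitch_um), w / (n_cols * pitch_um))
        return cls(n_rows=n_rows, n_cols=n_cols, pitch_um=pitch_um,
                   px_per_um=px_per_um, **kw)


@dataclass(frozen=True)
class Patch:
    """One electrode's image patch: half-open pixel bounds [r0, r1) x [c0, c1)."""

    row: int
    col: int
    r0: int
    r1: int
    c0: int
    c1: int

    @property
    def center(self):
        return ((self.r0 + self.r1 - 1) / 2.0, (self.c0 + self.c1 - 1) / 2.0)

    @property
    def shape(self):
        return (self.r1 - self.r0, self.c1 - self.c0)


@dataclass(frozen=True)
class Segment:
    """A detected line segment in patch-local pixel coordinates."""

    p0: tuple  # (row, col)
    p1: tuple
    votes: int


@dataclass(frozen=True)
class SegmentEndpoint:
    """Endpoint geometry used to fit one Von Mises component."""

    angle: float  # bearing on the circumscribing circle, in [0, 2*pi)
    boundary_distance: float  # px to the nearest patch side
    hough_votes: int


@dataclass(frozen=True)
class VonMisesComponent:
    mean: float
    kappa: float
    weight: float


@dataclass
class HeatKernelResult:
    adjacency: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    time: float
    heat: np.ndarray
    method: str = "eig"

    @property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.adjacency.sum(axis=1)) - self.adjacency


@dataclass
class StructuralGraph:
    """Thresholded structural connectivity over seed electrodes."""

    seeds: np.ndarray  # node indices with >= 1 neuron
    strength: np.ndarray  # normalized heat, seeds x seeds, zero diagonal
    edges: np.ndarray  # (m, 2) positions into `seeds`
    edge_length_um: np.ndarray
    distance_um: np.ndarray = field(default=None)  # seeds x seeds, inf if unreachable
    distance_norm: np.ndarray = field(default=None)
    reachable: np.ndarray = field(default=None)
    sc_threshold: float = 0.0

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# image partition and segment detection
# ---------------------------------------------------------------------------

def partition_image(image: np.ndarray, grid: ElectrodeGrid) -> list[Patch]:
    """Tile the image into one patch per electrode.

    Patch boundaries are the rounded positions of the ideal (float) lattice
    so the patches tile the active area without overlap.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise DimensionError("expected a single-channel (grayscale) image")
    h, w = image.shape
    size = grid.patch_px
    r_edges = np.round(grid.offset_row_px + size * np.arange(grid.n_rows + 1)).astype(int)
    c_edges = np.round(grid.offset_col_px + size * np.arange(grid.n_cols + 1)).astype(int)
    if r_edges[0] < 0 or c_edges[0] < 0 or r_edges[-1] > h or c_edges[-1] > w:
        raise DimensionError(
            f"image {image.shape} smaller than the grid extent "
            f"(rows {r_edges[0]}..{r_edges[-1]}, cols {c_edges[0]}..{c_edges[-1]})"
        )
    patches = []
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            patches.append(Patch(i, j, r_edges[i], r_edges[i + 1],
                                 c_edges[j], c_edges[j + 1]))
    return patches


def detect_segments(patch_image: np.ndarray, hough: HoughConfig | None = None,
                    rng=None) -> list[Segment]:
    """Detect neurite-like line segments in one patch.

    Uses a Canny edge map followed by the probabilistic Hough transform.
    Each segment's vote count is the number of edge pixels supporting it
    (edge pixels within one pixel of the rasterized segment).
    """
    hough = hough or HoughConfig()
    rng = np.random.default_rng(rng if rng is not None else 0)
    patch_image = np.asarray(patch_image, dtype=float)
    if patch_image.size == 0 or np.ptp(patch_image) == 0:
        return []
    edges = canny(patch_image, sigma=hough.canny_sigma)
    if not edges.any():
        return []
    lines = probabilistic_hough_line(
        edges, threshold=hough.threshold, line_length=hough.line_length,
        line_gap=hough.line_gap, rng=rng)
    # pad so the 1-px support neighborhood never indexes out of bounds
    padded = np.pad(edges, 1)
    segments = []
    for (x0, y0), (x1, y1) in lines:  # skimage returns (col, row)
        rr, cc = draw_line(y0, x0, y1, x1)
        support = np.zeros(padded.shape, dtype=bool)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                support[rr + 1 + dr, cc + 1 + dc] = True
        votes = int(np.count_nonzero(padded & support))
        segments.append(Segment(p0=(y0, x0), p1=(y1, x1), votes=max(votes, 1)))
    return segments


# ---------------------------------------------------------------------------
# Von Mises mixture fitting and discretization
# ---------------------------------------------------------------------------

def _endpoint_geometry(point, patch_shape) -> tuple[float, float]:
    """Bearing of an endpoint on the circumscribing circle and its distance
    to the nearest patch side (both in patch-local pixel coordinates)."""
    r, c = point
    h, w = patch_shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    # +x = increasing col, +y = decreasing row (counterclockwise angles)
    angle = float(np.arctan2(-(r - cr), c - cc)) % (2 * np.pi)
    d = float(min(r, h - 1 - r, c, w - 1 - c))
    return angle, max(d, 0.0)


def segment_endpoints(segments, patch_shape) -> list[SegmentEndpoint]:
    eps = []
    for seg in segments:
        for point in (seg.p0, seg.p1):
            angle, d = _endpoint_geometry(point, patch_shape)
            eps.append(SegmentEndpoint(angle, d, seg.votes))
    return eps


def fit_vmm(segments, patch_shape, kappa_scale=10.0, kappa_eps=1.0,
            kappa_max=1.0e4) -> list[VonMisesComponent]:
    """Fit one Von Mises component per segment endpoint.

    The mean is the endpoint's bearing on the circle circumscribing the
    patch; the concentration is ``kappa_scale / (d + kappa_eps)`` with d the
    endpoint-to-boundary distance (far endpoints -> diffuse exit angle);
    mixture weights are the normalized Hough votes, each segment
    contributing its votes to both of its endpoints.
    """
    if kappa_scale <= 0:
        raise ContractError("kappa_scale must be positive")
    if not segments:
        return []
    endpoints = segment_endpoints(segments, patch_shape)
    total_votes = float(sum(ep.hough_votes for ep in endpoints))
    comps = []
    for ep in endpoints:
        kappa = min(kappa_scale / (ep.boundary_distance + kappa_eps), kappa_max)
        comps.append(VonMisesComponent(mean=ep.angle, kappa=kappa,
                                       weight=ep.hough_votes / total_votes))
    return comps


def _vm_sector_mass(mu, kappa, lo, hi):
    """Probability mass of a Von Mises(mu, kappa) on the arc [lo, hi]
    (hi - lo < 2*pi)."""
    if kappa < 1e-12:
        return (hi - lo) / (2 * np.pi)
    # re-center so scipy's cdf (defined on [loc-pi, loc+pi]) applies
    a = (lo - mu + np.pi) % (2 * np.pi) - np.pi
    b = (hi - mu + np.pi) % (2 * np.pi) - np.pi
    if a <= b:
        return float(vonmises.cdf(b, kappa) - vonmises.cdf(a, kappa))
    return float(1.0 - (vonmises.cdf(a, kappa) - vonmises.cdf(b, kappa)))


def discretize_vmm(components) -> np.ndarray:
    """Integrate the mixture density over eight 45-degree sectors centered on
    the neighbor bearings.  Returns the 8-bin probability histogram (all
    zeros for an empty mixture)."""
    probs = np.zeros(N_DIRECTIONS)
    if not components:
        return probs
    total_w = sum(c.weight for c in components)
    if not np.isclose(total_w, 1.0, atol=1e-8):
        raise ContractError("mixture weights must sum to 1")
    half = np.pi / 8
    for k in range(N_DIRECTIONS):
        center = k * np.pi / 4
        probs[k] = sum(
            c.weight * _vm_sector_mass(c.mean, c.kappa, center - half, center + half)
            for c in components
        )
    return probs


def compute_directional_features(image, grid: ElectrodeGrid,
                                 hough: HoughConfig | None = None,
                                 kappa_scale=10.0, kappa_eps=1.0,
                                 kappa_max=1.0e4, seed=0) -> np.ndarray:
    """Per-electrode 8-bin neurite exit-direction histograms.

    Returns an (n_rows, n_cols, 8) array; all-zero rows mark patches where
    no segment was found.
    """
    image = np.asarray(image, dtype=float)
    patches = partition_image(image, grid)
    features = np.zeros((grid.n_rows, grid.n_cols, N_DIRECTIONS))
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(patches))
    for patch, child in zip(patches, child_seeds):
        sub = image[patch.r0:patch.r1, patch.c0:patch.c1]
        segs = detect_segments(sub, hough, rng=np.random.default_rng(child))
        if not segs:
            continue
        comps = fit_vmm(segs, patch.shape, kappa_scale, kappa_eps, kappa_max)
        features[patch.row, patch.col] = discretize_vmm(comps)
    return features


# ---------------------------------------------------------------------------
# adjacency and graph heat kernel
# ---------------------------------------------------------------------------

def build_adjacency(features: np.ndarray, grid: ElectrodeGrid) -> np.ndarray:
    """Symmetrized weighted lattice adjacency from the directional features.

    For 8-connected lattice neighbors x, y the weight is the sum of the two
    directed histogram entries, A(x, y) = f_x[x->y] + f_y[y->x]; all other
    entries are zero and the diagonal is zero.
    """
    features = np.asarray(features)
    if features.shape != (grid.n_rows, grid.n_cols, N_DIRECTIONS):
        raise DimensionError("features shape does not match the grid")
    n = grid.n_electrodes
    A = np.zeros((n, n))
    rows, cols = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols),
                             indexing="ij")
    for k, (dr, dc) in enumerate(DIRECTION_STEPS):
        nr, nc = rows + dr, cols + dc
        ok = (nr >= 0) & (nr < grid.n_rows) & (nc >= 0) & (nc < grid.n_cols)
        src = grid.node_index(rows[ok], cols[ok])
        dst = grid.node_index(nr[ok], nc[ok])
        opp = (k + 4) % N_DIRECTIONS
        A[src, dst] = (features[rows[ok], cols[ok], k]
                       + features[nr[ok], nc[ok], opp])
    return A


def heat_kernel(A: np.ndarray, t: float, method: str = "eig") -> HeatKernelResult:
    """Heat kernel h_t = exp(-t * L) of the graph Laplacian L = D - A.

    ``method='eig'`` uses the dense eigendecomposition
    h_t(x, y) = sum_i exp(-lambda_i t) phi_i(x) phi_i(y); ``method='expm'``
    uses the scaled-and-squared matrix exponential (for graphs too large to
    eigendecompose).  Rows of h_t sum to 1 (heat conservation) and h_0 is
    the identity.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ContractError("adjacency must be a square matrix")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ContractError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ContractError("adjacency must be non-negative")
    if t < 0:
        raise ContractError("diffusion time must be non-negative")
    L = np.diag(A.sum(axis=1)) - A
    if method == "eig":
        lam, phi = eigh(L)
        lam = np.clip(lam, 0.0, None)
        heat = (phi * np.exp(-lam * t)) @ phi.T
        heat = (heat + heat.T) / 2.0
    elif method == "expm":
        lam = phi = None
        heat = expm(-t * L)
        heat = (heat + heat.T) / 2.0
    else:
        raise ContractError(f"unknown heat-kernel method {method!r}")
    return HeatKernelResult(adjacency=A, eigenvalues=lam, eigenvectors=phi,
                            time=t, heat=heat, method=method)


def propagate_and_normalize(hk: HeatKernelResult, seeds,
                            mode: str = "offdiag") -> tuple[np.ndarray, np.ndarray]:
    """Restrict the heat map to seed electrodes and max-normalize it.

    ``mode='offdiag'`` divides by the maximum off-diagonal seed-pair entry
    (the diagonal self-heat always dominates and would otherwise compress
    every candidate link toward zero); ``mode='full'`` divides by the full
    restricted-matrix maximum.  The returned map has a zero diagonal and
    entries in [0, 1].

    Returns ``(seeds, normalized_map)``.
    """
    seeds = np.asarray(sorted(set(int(s) for s in np.atleast_1d(seeds))))
    if seeds.size == 0:
        raise ContractError("seed set must be non-empty")
    sub = hk.heat[np.ix_(seeds, seeds)].copy()
    off = sub.copy()
    np.fill_diagonal(off, 0.0)
    if mode == "offdiag":
        mx = off.max() if off.size else 0.0
    elif mode == "full":
        mx = sub.max()
    else:
        raise ContractError(f"unknown normalization mode {mode!r}")
    norm = off / mx if mx > 0 else off
    np.clip(norm, 0.0, 1.0, out=norm)
    return seeds, norm


def build_structural_graph(seeds, norm_map, grid: ElectrodeGrid,
                           sc_threshold: float) -> StructuralGraph:
    """Threshold the normalized heat map into a discrete SC edge set."""
    seeds = np.asarray(seeds)
    norm_map = np.asarray(norm_map)
    iu = np.triu_indices(len(seeds), k=1)
    keep = norm_map[iu] >= sc_threshold
    edges = np.stack([iu[0][keep], iu[1][keep]], axis=1)
    lengths = grid.euclid_um(seeds[edges[:, 0]], seeds[edges[:, 1]]) \
        if len(edges) else np.zeros(0)
    return StructuralGraph(seeds=seeds, strength=norm_map, edges=edges,
                           edge_length_um=lengths, sc_threshold=sc_threshold)


def structural_distances(sc: StructuralGraph) -> StructuralGraph:
    """Shortest-path structural distances between all seed pairs.

    Edge lengths are euclidean inter-electrode-center distances in um;
    d_xy is the minimal total length over paths in the SC graph.
    Unreachable pairs get d = inf, a cleared ``reachable`` flag, and
    normalized distance 1 (maximum penalty).  Finite distances are
    normalized by the maximum finite off-diagonal distance.
    """
    n = len(sc.seeds)
    if len(sc.edges):
        w = sparse.csr_matrix(
            (sc.edge_length_um, (sc.edges[:, 0], sc.edges[:, 1])), shape=(n, n))
        w = w + w.T
        dist = dijkstra(w, directed=False)
    else:
        dist = np.full((n, n), np.inf)
        np.fill_diagonal(dist, 0.0)
    reachable = np.isfinite(dist)
    finite = dist[reachable & ~np.eye(n, dtype=bool)]
    dmax = finite.max() if finite.size else 1.0
    dn = np.where(reachable, dist / dmax if dmax > 0 else dist, 1.0)
    np.clip(dn, 0.0, 1.0, out=dn)
    sc.distance_um = dist
    sc.distance_norm = dn
    sc.reachable = reachable
    return sc
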