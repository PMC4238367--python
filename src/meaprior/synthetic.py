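"""Ground-truth synthetic cultures: image, spike trains, and truth graphs.

The generator emulates a sparse dissociated culture on a regular
high-density electrode lattice: a few hundred to a thousand neurons, one
per electrode, joined by curved neurite polylines to spatially proximal
neighbors.  A grayscale image renders the neurites (bright-on-dark, PSF
blur, additive noise) over the lattice; spike trains are homogeneous
background Poisson processes plus causally coupled firing across a subset
of the structural edges, with conduction delays set by the neurite path
length at a physiological propagation velocity (default 200 mm/s, always
compatible with the 400 mm/s plausibility bound).  A configurable number
of "noise electrodes" spike at the background rate without holding any
neuron, reproducing the spurious activity that node pruning removes in
real recordings.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, line_aa

from .errors import ContractError
from .functional import SpikeTrain
from .structural import ElectrodeGrid

V_MAX_UM_S = 400e3  # physiological upper bound on propagation velocity


@dataclass(frozen=True)
class StructuralEdgeTruth:
    a: int  # neuron indices
    b: int
    polyline_um: np.ndarray  # (m, 2) points, (row_um, col_um)
    length_um: float


@dataclass(frozen=True)
class FunctionalLinkTruth:
    source: int  # neuron index
    target: int
    delay_s: float
    length_um: float


@dataclass
class SyntheticNetwork:
    grid: ElectrodeGrid
    neuron_electrodes: np.ndarray  # (n, 2) distinct (row, col)
    neuron_pos_um: np.ndarray  # (n, 2) positions, (row_um, col_um)
    structural_edges: list
    functional_links: list
    noise_electrodes: list  # (row, col) spiking electrodes with no neuron
    velocity_um_s: float
    seed: int

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_electrodes)

    def neuron_map(self) -> dict:
        """(row, col) -> neuron count, total over all spiking electrodes."""
        m = {}
        for r, c in self.neuron_electrodes:
            m[(int(r), int(c))] = m.get((int(r), int(c)), 0) + 1
        for rc in self.noise_electrodes:
            m.setdefault(tuple(rc), 0)
        return m

    def electrode_of(self, neuron: int) -> tuple:
        r, c = self.neuron_electrodes[neuron]
        return int(r), int(c)

    def structural_pairs(self) -> set:
        """Unordered electrode pairs connected by a ground-truth neurite."""
        out = set()
        for e in self.structural_edges:
            out.add(frozenset((self.electrode_of(e.a), self.electrode_of(e.b))))
        return out

    def functional_pairs(self) -> set:
        """Unordered electrode pairs carrying a ground-truth coupling."""
        out = set()
        for l in self.functional_links:
            out.add(frozenset((self.electrode_of(l.source),
                               self.electrode_of(l.target))))
        return out

    def truth_json(self) -> dict:
        return {
            "seed": self.seed,
            "grid": {"n_rows": self.grid.n_rows, "n_cols": self.grid.n_cols,
                     "pitch_um": self.grid.pitch_um},
            "velocity_um_s": self.velocity_um_s,
            "neurons": [[int(r), int(c)] for r, c in self.neuron_electrodes],
            "noise_electrodes": [list(rc) for rc in self.noise_electrodes],
            "structural_edges": [[int(e.a), int(e.b), float(e.length_um)]
                                 for e in self.structural_edges],
            "functional_links": [[int(l.source), int(l.target),
                                  float(l.delay_s), float(l.length_um)]
                                 for l in self.functional_links],
        }

    def write_truth(self, path):
        Path(path).write_text(json.dumps(self.truth_json(), indent=1))


def generate_network(n_neurons: int = 1000,
                     grid: ElectrodeGrid | None = None,
                     edge_density: float = 0.3,
                     radius_pitches: float = 3.0,
                     functional_fraction: float = 0.5,
                     curvature: float = 0.12,
                     noise_electrode_fraction: float = 0.1,
                     velocity_mm_s: float = 200.0,
                     synaptic_delay_s: float = 1e-3,
                     seed: int = 0) -> SyntheticNetwork:
    """Sample a ground-truth culture.

    Neurons occupy distinct electrodes (positions jittered within the
    recording area); each pair of neurons closer than
    ``radius_pitches * pitch`` is joined by a neurite polyline with
    probability ``edge_density``; a ``functional_fraction`` subset of the
    neurites carries a directed coupling with delay = synaptic latency +
    path length / velocity.  Polyline curvature guarantees path length >=
    straight-line distance, and the synaptic latency is non-negative, so
    every delay respects the 400 mm/s bound.
    """
    grid = grid or ElectrodeGrid()
    if n_neurons < 2:
        raise ContractError("need at least two neurons")
    if n_neurons + int(round(noise_electrode_fraction * n_neurons)) > grid.n_electrodes:
        raise ContractError("more neurons than electrodes")
    rng = np.random.default_rng(seed)
    pitch = grid.pitch_um
    n_noise = int(round(noise_electrode_fraction * n_neurons))
    idx = rng.choice(grid.n_electrodes, size=n_neurons + n_noise, replace=False)
    rows, cols = grid.node_rc(idx[:n_neurons])
    electrodes = np.stack([rows, cols], axis=1)
    centers = grid.centers_um(idx[:n_neurons])
    pos = centers + rng.uniform(-0.2 * pitch, 0.2 * pitch, size=centers.shape)
    noise_rc = [tuple(int(v) for v in rc)
                for rc in np.stack(grid.node_rc(idx[n_neurons:]), axis=1)]

    radius = radius_pitches * pitch
    edges = []
    for a in range(n_neurons):
        d = np.linalg.norm(pos[a + 1:] - pos[a], axis=1)
        for off in np.flatnonzero(d <= radius):
            b = a + 1 + off
            if rng.random() >= edge_density:
                continue
            p0, p1 = pos[a], pos[b]
            straight = p1 - p0
            length = np.linalg.norm(straight)
            perp = np.array([-straight[1], straight[0]]) / max(length, 1e-9)
            mid = (p0 + p1) / 2 + perp * rng.normal(0.0, curvature * length)
            poly = np.stack([p0, mid, p1])
            plen = float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
            edges.append(StructuralEdgeTruth(a, b, poly, plen))

    v_um_s = velocity_mm_s * 1e3
    if v_um_s > V_MAX_UM_S:
        raise ContractError("velocity exceeds the physiological bound")
    links = []
    for e in edges:
        if rng.random() < functional_fraction:
            src, tgt = (e.a, e.b) if rng.random() < 0.5 else (e.b, e.a)
            delay = synaptic_delay_s + e.length_um / v_um_s
            links.append(FunctionalLinkTruth(src, tgt, delay, e.length_um))
    return SyntheticNetwork(grid=grid, neuron_electrodes=electrodes,
                            neuron_pos_um=pos, structural_edges=edges,
                            functional_links=links, noise_electrodes=noise_rc,
                            velocity_um_s=v_um_s, seed=seed)


def render_image(network: SyntheticNetwork, psf_sigma: float = 1.0,
                 noise_level: float = 0.05, patch_px: int = 16,
                 seed: int = 0) -> np.ndarray:
    """Rasterize the culture as a grayscale image in [0, 1].

    Neurite polylines are drawn bright-on-dark with anti-aliasing, soma
    blobs are placed at the neuron positions, and the frame is blurred by
    a Gaussian PSF with additive Gaussian noise.
    """
    grid = network.grid
    h = grid.n_rows * patch_px
    w = grid.n_cols * patch_px
    scale = patch_px / grid.pitch_um  # px per um
    img = np.zeros((h, w))

    def to_px(p):
        return int(round(p[0] * scale)), int(round(p[1] * scale))

    for e in network.structural_edges:
        pts = [to_px(p) for p in e.polyline_um]
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc, val = line_aa(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            img[rr[ok], cc[ok]] = np.maximum(img[rr[ok], cc[ok]], val[ok])
    soma_r = max(1, int(round(0.12 * patch_px)))
    for p in network.neuron_pos_um:
        rr, cc = disk(to_px(p), soma_r, shape=img.shape)
        img[rr, cc] = 1.0
    if psf_sigma > 0:
        img = gaussian_filter(img, psf_sigma)
        mx = img.max()
        if mx > 0:
            img /= mx
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_level, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def simulate_spikes(network: SyntheticNetwork, T: float = 300.0,
                    bg_rate: float = 1.0, coupling_p: float = 0.5,
                    delay_jitter: float = 0.5e-3, seed: int = 0,
                    max_generations: int = 3) -> dict:
    """Simulate per-electrode spike trains.

    Every neuron fires background spikes as a homogeneous Poisson process
    at ``bg_rate``; each spike of a coupling's source elicits a target
    spike with probability ``coupling_p`` after the link delay plus a
    uniform jitter in [-delay_jitter, +delay_jitter] (clipped so the
    delay never beats the 400 mm/s bound).  Elicited spikes propagate
    for up to ``max_generations`` synaptic hops.  Per-electrode trains
    are merged, sorted, and deduplicated within one sampling period.
    Noise electrodes fire independent background Poisson trains.
    """
    if T <= 0:
        raise ContractError("recording length must be positive")
    if not 0.0 <= coupling_p <= 1.0:
        raise ContractError("coupling probability must lie in [0, 1]")
    if bg_rate < 0:
        raise ContractError("background rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = network.n_neurons
    out_links = [[] for _ in range(n)]
    for l in network.functional_links:
        min_delay = l.length_um / V_MAX_UM_S
        out_links[l.source].append((l.target, l.delay_s, min_delay))

    spikes = [[] for _ in range(n)]
    heap = []
    for i in range(n):
        k = rng.poisson(bg_rate * T)
        for t in np.sort(rng.uniform(0.0, T, size=k)):
            heapq.heappush(heap, (float(t), i, 0))
    while heap:
        t, i, gen = heapq.heappop(heap)
        spikes[i].append(t)
        if gen >= max_generations:
            continue
        for tgt, delay, min_delay in out_links[i]:
            if rng.random() < coupling_p:
                d = max(delay + rng.uniform(-delay_jitter, delay_jitter),
                        min_delay)
                t2 = t + d
                if t2 <= T:
                    heapq.heappush(heap, (float(t2), tgt, gen + 1))

    dt = 1.0 / network.grid.sampling_rate_hz
    trains = {}
    for i in range(n):
        times = np.sort(np.asarray(spikes[i]))
        if times.size:
            keep = np.concatenate([[True], np.diff(times) >= dt])
            times = times[keep]
        rc = network.electrode_of(i)
        trains[rc] = SpikeTrain(rc[0], rc[1], times, T)
    for rc in network.noise_electrodes:
        k = rng.poisson(bg_rate * T)
        times = np.sort(rng.uniform(0.0, T, size=k))
        trains[tuple(rc)] = SpikeTrain(rc[0], rc[1], times, T)
    return trains
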