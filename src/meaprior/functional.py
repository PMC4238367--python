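"""Functional connectivity from spike trains.

For every pair of active electrodes a cross-correlogram is computed in
0.5 ms bins: C(tau) is the number of spike pairs whose time difference
falls in the bin centered at tau, divided by sqrt(N_x * N_y).  The peak of
the correlogram (value, lag, raw coincidence count) summarizes the link.
Links whose peak latency is shorter than the straight-line electrode
distance divided by the maximum propagation velocity of in-vitro
preparations (400 mm/s) are physiologically implausible and flagged.
Statistical significance is assessed against a dithering null model: spike
times jittered by i.i.d. uniform +-5 ms offsets, repeated 100 times over a
random sample of pairs; the significance threshold C_s is the empirical
95th percentile of the pooled null peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .structural import ElectrodeGrid


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds) recorded at one electrode."""

    row: int
    col: int
    times: np.ndarray
    t_r: float  # recording length, s

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and (times.min() < 0 or times.max() > self.t_r):
            raise ContractError("spike times must lie in [0, t_r]")
        if np.any(np.diff(times) < 0):
            raise ContractError("spike times must be sorted")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def mfr(self) -> float:
        """Mean firing rate N / t_r in Hz."""
        return self.n_spikes / self.t_r if self.t_r > 0 else 0.0


@dataclass
class Correlogram:
    lags: np.ndarray  # bin centers, s
    counts: np.ndarray  # raw coincidence counts per bin
    values: np.ndarray  # counts / sqrt(Nx * Ny)
    n_x: int
    n_y: int
    bin_width: float


@dataclass
class FunctionalLink:
    x: tuple  # (row, col)
    y: tuple
    c_p: float  # correlogram peak value
    c_tau: float | None  # peak lag, s (None when the correlogram is empty)
    c_o: int  # raw coincidence count at the peak
    euclid_um: float = np.nan
    survives_velocity_filter: bool = True
    significant_vs_cs: bool = False


@dataclass
class NullModel:
    pairs: list  # sampled ((row, col), (row, col)) pairs
    peaks: np.ndarray  # (n_pairs, reps) null peak values
    c_s: float  # significance threshold at the configured p-value
    jitter_s: float
    reps: int
    p_value: float
    seed: int | None = None
    pair_distance_norm: np.ndarray = field(default=None)  # filled at integration


# ---------------------------------------------------------------------------
# correlogram and peak
# ---------------------------------------------------------------------------

def _pair_diffs(x: np.ndarray, y: np.ndarray, max_abs: float) -> np.ndarray:
    """All differences u - t (u in y, t in x) with |diff| <= max_abs."""
    lo = np.searchsorted(y, x - max_abs, side="left")
    hi = np.searchsorted(y, x + max_abs, side="right")
    lens = hi - lo
    total = int(lens.sum())
    if total == 0:
        return np.zeros(0)
    cum = np.cumsum(lens)
    flat = np.arange(total) - np.repeat(cum - lens, lens) + np.repeat(lo, lens)
    return y[flat] - np.repeat(x, lens)


def cross_correlogram(train_x: SpikeTrain, train_y: SpikeTrain,
                      bin_width: float = 0.5e-3,
                      window: float = 50e-3) -> Correlogram:
    """Cross-correlogram of two spike trains.

    Bin k (k = -K..K, K = round(window / bin_width)) is centered at
    k * bin_width and covers differences u - t in
    [k*b - b/2, k*b + b/2); the value is the count divided by
    sqrt(N_x * N_y).
    """
    if train_x.n_spikes == 0 or train_y.n_spikes == 0:
        raise ContractError("both spike trains must contain at least one spike")
    K = int(round(window / bin_width))
    diffs = _pair_diffs(train_x.times, train_y.times, window + bin_width)
    counts = np.zeros(2 * K + 1, dtype=np.int64)
    if diffs.size:
        k = np.floor(diffs / bin_width + 0.5).astype(np.int64)
        ok = np.abs(k) <= K
        counts = np.bincount(k[ok] + K, minlength=2 * K + 1)
    lags = np.arange(-K, K + 1) * bin_width
    norm = np.sqrt(train_x.n_spikes * train_y.n_spikes)
    return Correlogram(lags=lags, counts=counts, values=counts / norm,
                       n_x=train_x.n_spikes, n_y=train_y.n_spikes,
                       bin_width=bin_width)


def peak(cg: Correlogram) -> tuple[float, float | None, int]:
    """Correlogram peak (C_P, C_tau, C_O).

    Ties at equal peak value are broken toward the smallest absolute lag,
    then toward the positive lag.  An all-zero correlogram yields
    (0.0, None, 0).
    """
    if cg.counts.sum() == 0 or cg.values.max() == 0:
        return 0.0, None, 0
    vmax = cg.values.max()
    cand = np.flatnonzero(cg.values == vmax)
    order = sorted(cand, key=lambda i: (abs(cg.lags[i]), cg.lags[i] < 0))
    best = order[0]
    return float(cg.values[best]), float(cg.lags[best]), int(cg.counts[best])


# ---------------------------------------------------------------------------
# functional graph, velocity filter, dithering null
# ---------------------------------------------------------------------------

def build_functional_links(trains: dict, grid: ElectrodeGrid,
                           bin_width: float = 0.5e-3, window: float = 50e-3,
                           keep_correlograms: bool = True):
    """Correlogram statistics for every unordered pair of active electrodes.

    ``trains`` maps (row, col) -> SpikeTrain; only electrodes with at least
    one spike enter the graph.  Returns (links, correlograms) where
    correlograms maps the unordered pair key to its Correlogram (x = the
    lexicographically smaller electrode).
    """
    active = sorted(k for k, tr in trains.items() if tr.n_spikes > 0)
    links, cgs = [], {}
    for i, a in enumerate(active):
        for b in active[i + 1:]:
            cg = cross_correlogram(trains[a], trains[b], bin_width, window)
            c_p, c_tau, c_o = peak(cg)
            d = float(grid.euclid_um(grid.node_index(*a), grid.node_index(*b)))
            links.append(FunctionalLink(x=a, y=b, c_p=c_p, c_tau=c_tau,
                                        c_o=c_o, euclid_um=d))
            if keep_correlograms:
                cgs[(a, b)] = cg
    return links, cgs


def velocity_filter(links, v_max_mm_s: float = 400.0):
    """Flag links whose peak latency is physiologically implausible.

    A link is discarded when |C_tau| < d / v_max, i.e., when a signal
    travelling at the maximal propagation velocity could not cover the
    straight-line inter-electrode distance within the observed lag.
    """
    v_um_s = v_max_mm_s * 1e3
    for link in links:
        if link.c_tau is None:
            link.survives_velocity_filter = False
        else:
            link.survives_velocity_filter = (
                abs(link.c_tau) >= link.euclid_um / v_um_s)
    return links


def _jitter_sorted(times: np.ndarray, jitter: float, t_r: float, rng) -> np.ndarray:
    j = times + rng.uniform(-jitter, jitter, size=times.size)
    np.clip(j, 0.0, t_r, out=j)
    j.sort()
    return j


def dither_null(trains: dict, pair_sample, jitter: float = 5e-3,
                reps: int = 100, p_value: float = 0.05,
                bin_width: float = 0.5e-3, window: float = 50e-3,
                seed: int | None = 0) -> NullModel:
    """Dithering null model and significance threshold C_s.

    Each repetition jitters every spike of both trains of each sampled
    pair by an i.i.d. uniform offset in [-jitter, +jitter] (clipped to the
    recording interval), recomputes the correlogram, and records its peak.
    C_s is the empirical (1 - p) quantile of the pooled null peaks.
    """
    if reps < 1:
        raise ContractError("reps must be >= 1")
    pair_sample = list(pair_sample)
    if not pair_sample:
        raise ContractError("pair sample must be non-empty")
    rng = np.random.default_rng(seed)
    peaks = np.zeros((len(pair_sample), reps))
    for pi, (a, b) in enumerate(pair_sample):
        tx, ty = trains[a], trains[b]
        for r in range(reps):
            jx = _jitter_sorted(tx.times, jitter, tx.t_r, rng)
            jy = _jitter_sorted(ty.times, jitter, ty.t_r, rng)
            cg = cross_correlogram(
                SpikeTrain(tx.row, tx.col, jx, tx.t_r),
                SpikeTrain(ty.row, ty.col, jy, ty.t_r), bin_width, window)
            peaks[pi, r] = cg.values.max()
    c_s = float(np.quantile(peaks.ravel(), 1.0 - p_value))
    return NullModel(pairs=pair_sample, peaks=peaks, c_s=c_s,
                     jitter_s=jitter, reps=reps, p_value=p_value, seed=seed)


def sample_null_pairs(trains: dict, n_pairs: int = 500, seed: int | None = 0):
    """Seeded random sample of active unordered electrode pairs."""
    active = sorted(k for k, tr in trains.items() if tr.n_spikes > 0)
    all_pairs = [(a, b) for i, a in enumerate(active) for b in active[i + 1:]]
    rng = np.random.default_rng(seed)
    if len(all_pairs) <= n_pairs:
        return all_pairs
    idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    return [all_pairs[i] for i in sorted(idx)]


def apply_significance(links, c_s: float):
    """Mark links with peak strictly above the C_s threshold."""
    for link in links:
        link.significant_vs_cs = bool(link.c_p > c_s)
    return links
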