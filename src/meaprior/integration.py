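"""Refinement of the functional graph with the structural prior.

Two stages: (1) electrodes with no neuron in their recording area are
pruned from the functional graph together with every incident link;
(2) the surviving links' normalized peaks are reweighted by the
normalized structural distance, W = C~_P ** (1 + d), and re-thresholded
against W_s, the 95th percentile of the identically reweighted null
peaks.  The exponent form penalizes weak correlations more strongly with
distance while leaving strong functional evidence nearly untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, InputError
from .functional import NullModel
from .structural import ElectrodeGrid, StructuralGraph


@dataclass
class RefinedLink:
    x: tuple
    y: tuple
    c_p: float
    c_p_norm: float  # C~_P in [0, 1]
    d_um: float  # structural (shortest-path) distance, um; inf if unreachable
    d_norm: float  # normalized distance in [0, 1]
    reachable: bool
    weight: float  # W = C~_P ** (1 + d_norm)
    significant_vs_ws: bool = False

    @property
    def label(self) -> str:
        return "retained" if self.significant_vs_ws else "discarded"


@dataclass
class AccountingReport:
    """Stage-by-stage link accounting for one network.

    Counts mirror the usual reporting convention: the initial estimate,
    the C_s-significant subset, the neuron-pruned subset, and the final
    reweighted, W_s-thresholded graph, with discard counts and one-decimal
    percentages relative to the initial estimate.
    """

    neurons: int
    sc_links: int
    fc_initial: int
    fc_above_cs: int
    fc_after_pruning: int
    fc_pruned_above_cs: int
    fc_final: int
    # both conventions for "initial": including or excluding links removed
    # by the velocity filter before significance testing
    fc_prefilter: int | None = None

    @staticmethod
    def _pct(part: int, whole: int) -> float:
        if whole <= 0:
            return 0.0
        return round(100.0 * part / whole, 1)

    @property
    def discarded_at_cs(self) -> int:
        return self.fc_initial - self.fc_above_cs

    @property
    def discarded_at_cs_pct(self) -> float:
        return self._pct(self.discarded_at_cs, self.fc_initial)

    @property
    def pruning_reduction_pct(self) -> float:
        return self._pct(self.fc_initial - self.fc_after_pruning, self.fc_initial)

    @property
    def discarded_final(self) -> int:
        return self.fc_initial - self.fc_final

    @property
    def discarded_final_pct(self) -> float:
        return self._pct(self.discarded_final, self.fc_initial)

    def to_dict(self) -> dict:
        return {
            "neurons": self.neurons,
            "sc_links": self.sc_links,
            "fc_links_initial_estimate": self.fc_initial,
            "fc_links_prefilter": self.fc_prefilter,
            "fc_links_above_cs": self.fc_above_cs,
            "discarded_fc_links_at_cs": self.discarded_at_cs,
            "discarded_fc_links_at_cs_pct": self.discarded_at_cs_pct,
            "fc_links_neurons_only": self.fc_after_pruning,
            "pruning_reduction_pct": self.pruning_reduction_pct,
            "fc_links_neurons_only_above_cs": self.fc_pruned_above_cs,
            "fc_links_final_estimate": self.fc_final,
            "discarded_fc_links_final": self.discarded_final,
            "discarded_fc_links_final_pct": self.discarded_final_pct,
        }


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune_no_neuron_nodes(links, neuron_map: dict):
    """Remove links incident to electrodes with zero neurons.

    ``neuron_map`` maps (row, col) -> neuron count and must cover every
    electrode appearing in the links.  Returns (kept_links, n_removed).
    """
    for link in links:
        for node in (link.x, link.y):
            if node not in neuron_map:
                raise InputError(f"electrode {node} missing from the neuron map")
    kept = [l for l in links
            if neuron_map[l.x] > 0 and neuron_map[l.y] > 0]
    return kept, len(links) - len(kept)


# ---------------------------------------------------------------------------
# normalization and reweighting
# ---------------------------------------------------------------------------

def reweight(c_p_norm: float, d_norm: float) -> float:
    """W = C~_P ** (1 + d): monotone increasing in the normalized peak,
    decreasing in the normalized structural distance, with W = C~_P at
    d = 0 and W = C~_P**2 at d = 1."""
    c = np.asarray(c_p_norm, dtype=float)
    d = np.asarray(d_norm, dtype=float)
    if np.any((c < 0) | (c > 1)) or np.any((d < 0) | (d > 1)):
        raise ContractError("reweight inputs must lie in [0, 1]")
    out = c ** (1.0 + d)
    return float(out) if out.ndim == 0 else out


def _distance_lookup(sc: StructuralGraph, grid: ElectrodeGrid):
    """Map (row, col) pair -> (d_um, d_norm, reachable) from the SC graph."""
    pos = {int(s): i for i, s in enumerate(sc.seeds)}

    def lookup(a, b):
        ia = pos.get(int(grid.node_index(*a)))
        ib = pos.get(int(grid.node_index(*b)))
        if ia is None or ib is None:
            return np.inf, 1.0, False
        d = sc.distance_um[ia, ib]
        return float(d), float(sc.distance_norm[ia, ib]), bool(sc.reachable[ia, ib])

    return lookup


def normalize_and_reweight(links, sc: StructuralGraph,
                           grid: ElectrodeGrid) -> tuple[list, float]:
    """Build RefinedLinks from pruned, velocity-filtered functional links.

    C~_P is each peak divided by the maximum peak over these links (the
    population entering refinement); d_norm comes from the structural
    distance table, with unreachable pairs assigned the maximum penalty
    d_norm = 1 and a cleared ``reachable`` flag.  Returns
    (refined_links, c_p_max) so the null model can be normalized with the
    same constant.
    """
    links = list(links)
    if not links:
        return [], 0.0
    c_max = max(l.c_p for l in links)
    lookup = _distance_lookup(sc, grid)
    refined = []
    for l in links:
        d_um, d_norm, reach = lookup(l.x, l.y)
        c_norm = l.c_p / c_max if c_max > 0 else 0.0
        refined.append(RefinedLink(
            x=l.x, y=l.y, c_p=l.c_p, c_p_norm=c_norm, d_um=d_um,
            d_norm=d_norm, reachable=reach,
            weight=reweight(c_norm, d_norm)))
    return refined, c_max


def reweighted_threshold(null_model: NullModel, sc: StructuralGraph,
                         grid: ElectrodeGrid, c_p_max: float) -> float:
    """Significance threshold W_s from the reweighted null model.

    Null peaks are normalized by the same maximum used for the observed
    links (values above the observed maximum clip to 1), reweighted with
    the structural distance of their own sampled electrode pair, and W_s
    is the empirical (1 - p) quantile of the pooled reweighted peaks.
    """
    lookup = _distance_lookup(sc, grid)
    d_norms = np.array([lookup(a, b)[1] for a, b in null_model.pairs])
    null_model.pair_distance_norm = d_norms
    if c_p_max > 0:
        norm_peaks = np.clip(null_model.peaks / c_p_max, 0.0, 1.0)
    else:
        norm_peaks = np.zeros_like(null_model.peaks)
    w_null = norm_peaks ** (1.0 + d_norms[:, None])
    return float(np.quantile(w_null.ravel(), 1.0 - null_model.p_value))


def apply_ws(refined_links, w_s: float):
    """Retain links whose reweighted weight reaches the W_s threshold."""
    for l in refined_links:
        l.significant_vs_ws = bool(l.weight >= w_s)
    return refined_links


def accounting(neurons: int, sc_links: int, fc_initial: int, fc_above_cs: int,
               fc_after_pruning: int, fc_pruned_above_cs: int, fc_final: int,
               fc_prefilter: int | None = None) -> AccountingReport:
    """Assemble the stage-count report; percentages are recomputed from the
    counts at one-decimal rounding."""
    counts = [neurons, sc_links, fc_initial, fc_above_cs, fc_after_pruning,
              fc_pruned_above_cs, fc_final]
    if any(c < 0 for c in counts):
        raise ContractError("counts must be non-negative")
    return AccountingReport(neurons=neurons, sc_links=sc_links,
                            fc_initial=fc_initial, fc_above_cs=fc_above_cs,
                            fc_after_pruning=fc_after_pruning,
                            fc_pruned_above_cs=fc_pruned_above_cs,
                            fc_final=fc_final, fc_prefilter=fc_prefilter)
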