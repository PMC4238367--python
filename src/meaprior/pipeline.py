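"""End-to-end orchestration of the structural/functional pipeline.

Stage order: directional features -> heat kernel -> structural graph and
distances -> cross-correlogram functional graph -> velocity filter ->
dithering null and C_s -> node pruning -> distance reweighting and W_s ->
link accounting -> feature extraction and SVM ranking.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as mio
from .classification import (ClassificationResult, correlogram_entropy,
                             extract_features, svm_feature_ranking)
from .config import PipelineConfig
from .errors import ContractError
from .functional import (apply_significance, build_functional_links,
                         dither_null, sample_null_pairs, velocity_filter)
from .integration import (accounting, apply_ws, normalize_and_reweight,
                          prune_no_neuron_nodes, reweighted_threshold)
from .structural import (ElectrodeGrid, build_adjacency,
                         build_structural_graph, compute_directional_features,
                         heat_kernel, propagate_and_normalize,
                         structural_distances)

log = logging.getLogger("meaprior")


@dataclass
class PipelineResult:
    grid: ElectrodeGrid
    features: np.ndarray
    sc: object
    links: list
    correlograms: dict
    null: object
    refined: list
    w_s: float
    c_p_max: float
    report: object
    feature_table: object = None
    classification: ClassificationResult | None = None

    def retained_pairs(self) -> set:
        return {frozenset((l.x, l.y)) for l in self.refined
                if l.significant_vs_ws}

    def cs_pairs(self) -> set:
        return {frozenset((l.x, l.y)) for l in self.links
                if l.survives_velocity_filter and l.significant_vs_cs}

    def sc_pairs(self) -> set:
        r, c = self.grid.node_rc(self.sc.seeds)
        out = set()
        for a, b in self.sc.edges:
            out.add(frozenset(((int(r[a]), int(c[a])), (int(r[b]), int(c[b])))))
        return out


def make_grid(config: PipelineConfig, image=None, t_r: float = 0.0) -> ElectrodeGrid:
    px_per_um = config.px_per_um
    if px_per_um is None:
        if image is None:
            px_per_um = 1.0
        else:
            h, w = np.asarray(image).shape[:2]
            px_per_um = min(h / (config.n_rows * config.pitch_um),
                            w / (config.n_cols * config.pitch_um))
    return ElectrodeGrid(
        n_rows=config.n_rows, n_cols=config.n_cols, pitch_um=config.pitch_um,
        sampling_rate_hz=config.sampling_rate_hz, recording_length_s=t_r,
        offset_row_px=config.offset_row_px, offset_col_px=config.offset_col_px,
        px_per_um=px_per_um)


def structural_stage(image, neuron_map: dict, config: PipelineConfig,
                     grid: ElectrodeGrid | None = None):
    """Directional features, heat kernel, SC graph and distance table."""
    grid = grid or make_grid(config, image=image)
    features = compute_directional_features(
        image, grid, hough=config.hough, kappa_scale=config.kappa_scale,
        kappa_eps=config.kappa_eps, kappa_max=config.kappa_max,
        seed=config.seed)
    A = build_adjacency(features, grid)
    method = "eig" if grid.n_electrodes <= 4096 else "expm"
    hk = heat_kernel(A, config.heat_time, method=method)
    seeds = sorted(int(grid.node_index(r, c))
                   for (r, c), n in neuron_map.items() if n > 0)
    if not seeds:
        raise ContractError("neuron map contains no electrode with a neuron")
    seeds, norm_map = propagate_and_normalize(hk, seeds,
                                              mode=config.normalize_mode)
    sc = build_structural_graph(seeds, norm_map, grid, config.sc_threshold)
    sc = structural_distances(sc)
    log.info("structural: %d seeds, %d SC links (threshold %.3g)",
             len(seeds), sc.n_edges, config.sc_threshold)
    return grid, features, hk, sc


def functional_stage(trains: dict, grid: ElectrodeGrid,
                     config: PipelineConfig):
    """Correlogram graph, velocity filter, dithering null and C_s."""
    bin_w = config.bin_ms * 1e-3
    window = config.window_ms * 1e-3
    links, cgs = build_functional_links(trains, grid, bin_w, window)
    links = velocity_filter(links, config.v_max_mm_s)
    pairs = sample_null_pairs(trains, config.null_pairs, seed=config.seed)
    null = dither_null(trains, pairs, jitter=config.jitter_ms * 1e-3,
                       reps=config.null_reps, p_value=config.p_value,
                       bin_width=bin_w, window=window,
                       seed=config.seed + 1)
    links = apply_significance(links, null.c_s)
    n_sig = sum(1 for l in links
                if l.survives_velocity_filter and l.significant_vs_cs)
    log.info("functional: %d links, C_s=%.4g, %d significant",
             len(links), null.c_s, n_sig)
    return links, cgs, null


def integration_stage(links, null, sc, grid: ElectrodeGrid, neuron_map: dict,
                      config: PipelineConfig, n_neurons: int | None = None):
    """Prune, reweight, re-threshold, and account for every stage."""
    prefilter = [l for l in links if l.c_p > 0]
    initial = [l for l in prefilter if l.survives_velocity_filter]
    above_cs = [l for l in initial if l.significant_vs_cs]
    pruned, _ = prune_no_neuron_nodes(initial, neuron_map)
    pruned_above_cs = [l for l in pruned if l.significant_vs_cs]
    refined, c_max = normalize_and_reweight(pruned, sc, grid)
    w_s = reweighted_threshold(null, sc, grid, c_max) if refined else 0.0
    refined = apply_ws(refined, w_s)
    final = [l for l in refined if l.significant_vs_ws]
    if n_neurons is None:
        n_neurons = sum(1 for n in neuron_map.values() if n > 0)
    report = accounting(
        neurons=n_neurons, sc_links=sc.n_edges, fc_initial=len(initial),
        fc_above_cs=len(above_cs), fc_after_pruning=len(pruned),
        fc_pruned_above_cs=len(pruned_above_cs), fc_final=len(final),
        fc_prefilter=len(prefilter))
    log.info("integration: initial=%d above_Cs=%d pruned=%d final=%d (W_s=%.4g)",
             len(initial), len(above_cs), len(pruned), len(final), w_s)
    return refined, w_s, c_max, report


def classification_stage(refined, correlograms, trains, t_r: float,
                         config: PipelineConfig):
    table = extract_features(refined, correlograms, trains, t_r)
    result = svm_feature_ranking(table, folds=config.cv_folds,
                                 seed=config.seed, C=config.svm_c)
    log.info("classification: best subset %s at %.1f%%, ACC_eta=%.1f%%",
             result.table.iloc[0]["features"],
             result.table.iloc[0]["mean_accuracy_pct"], result.acc_eta)
    return table, result


def run_pipeline(config: PipelineConfig, image, trains: dict,
                 neuron_map: dict, out_dir=None, classify: bool = True,
                 n_neurons: int | None = None) -> PipelineResult:
    """Run every stage and optionally write the artifact bundle."""
    t_r = max((tr.t_r for tr in trains.values()), default=0.0)
    grid, features, hk, sc = structural_stage(image, neuron_map, config)
    links, cgs, null = functional_stage(trains, grid, config)
    refined, w_s, c_max, report = integration_stage(
        links, null, sc, grid, neuron_map, config, n_neurons=n_neurons)
    table = result = None
    if classify and refined:
        labels = {l.label for l in refined}
        if len(labels) == 2:
            table, result = classification_stage(refined, cgs, trains, t_r, config)
        else:
            log.info("classification skipped: only one link class present")
    res = PipelineResult(grid=grid, features=features, sc=sc, links=links,
                         correlograms=cgs, null=null, refined=refined,
                         w_s=w_s, c_p_max=c_max, report=report,
                         feature_table=table, classification=result)
    if out_dir is not None:
        write_bundle(Path(out_dir), res, config)
    return res


def write_bundle(out_dir: Path, res: PipelineResult, config: PipelineConfig):
    out_dir.mkdir(parents=True, exist_ok=True)
    mio.write_features_npz(out_dir / "directional_features.npz", res.features)
    mio.write_structural_edges(out_dir / "structural_edges.csv", res.sc, res.grid)
    mio.write_distance_table(out_dir / "distance_table.csv", res.sc, res.grid)
    entropies = {}
    for key, cg in res.correlograms.items():
        if cg.values.sum() > 0:
            entropies[key] = correlogram_entropy(cg.values)
    mio.functional_links_frame(res.links, entropies).to_csv(
        out_dir / "fc_links.csv", index=False)
    mio.refined_links_frame(res.refined).to_csv(
        out_dir / "refined_links.csv", index=False)
    mio.write_null_model(out_dir / "null_model.npz", res.null)
    mio.write_json(out_dir / "null_summary.json",
                   mio.null_summary_json(res.null))
    mio.write_graphml(out_dir / "structural_graph.graphml", res.sc, res.grid)
    if res.feature_table is not None:
        res.feature_table.to_csv(out_dir / "link_features.csv", index=False)
    if res.classification is not None:
        res.classification.table.to_csv(out_dir / "svm_ranking.csv", index=False)
    report = {
        "accounting": res.report.to_dict(),
        "W_s": res.w_s,
        "C_s": res.null.c_s,
        "C_P_max": res.c_p_max,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
    }
    if res.classification is not None:
        report["ACC_eta"] = res.classification.acc_eta
    mio.write_json(out_dir / "report.json", report)


# ---------------------------------------------------------------------------
# recovery scoring against a ground-truth pair set
# ---------------------------------------------------------------------------

def link_recovery(predicted: set, truth: set) -> dict:
    """Precision/recall of a predicted unordered-pair set against truth."""
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return {"tp": tp, "n_predicted": len(predicted), "n_truth": len(truth),
            "precision": precision, "recall": recall}
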