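"""Readers and writers for the pipeline's on-disk formats.

Images are single-channel TIFF or PNG; spike trains travel as event CSV
(columns row, col, time_s) or as an HDF5 container with one time array
per electrode and recording attributes; graphs and link tables are CSV
with an optional GraphML export.  Every writer/reader pair round-trips
losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .functional import FunctionalLink, NullModel, SpikeTrain
from .integration import RefinedLink
from .structural import StructuralGraph


def _require(path) -> Path:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    return path


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Load a grayscale culture image as float in [0, 1]."""
    path = _require(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:
        if img.shape[2] not in (1, 3, 4):
            raise InputError(f"cannot interpret image with shape {img.shape}")
        img = img[..., :3].mean(axis=2) if img.shape[2] > 1 else img[..., 0]
    if img.ndim != 2:
        raise InputError(f"expected a 2-D image, got shape {img.shape}")
    img = img.astype(float)
    if img.max() > 1.0:
        img /= np.iinfo(np.uint16).max if img.max() > 255 else 255.0
    return img


def write_image(path, image: np.ndarray):
    path = Path(path)
    image = np.asarray(image, dtype=np.float32)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, (np.clip(image, 0, 1) * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def write_spikes_csv(path, trains: dict):
    rows = []
    for (r, c), tr in sorted(trains.items()):
        for t in tr.times:
            rows.append((r, c, t))
    df = pd.DataFrame(rows, columns=["row", "col", "time_s"])
    df.to_csv(path, index=False, float_format="%.9f")


def read_spikes_csv(path, t_r: float, electrodes=None) -> dict:
    """Read an event CSV into SpikeTrains.

    ``electrodes`` optionally lists (row, col) electrodes that must appear
    (with empty trains) even if they emitted no event.
    """
    df = pd.read_csv(_require(path))
    missing = {"row", "col", "time_s"} - set(df.columns)
    if missing:
        raise InputError(f"spike CSV missing columns {sorted(missing)}")
    trains = {}
    for (r, c), g in df.groupby(["row", "col"]):
        trains[(int(r), int(c))] = SpikeTrain(
            int(r), int(c), np.sort(g["time_s"].to_numpy()), t_r)
    for rc in electrodes or []:
        trains.setdefault(tuple(rc), SpikeTrain(rc[0], rc[1], np.zeros(0), t_r))
    return trains


def write_spikes_hdf5(path, trains: dict, f_s: float, t_r: float):
    with h5py.File(path, "w") as fh:
        fh.attrs["f_s"] = f_s
        fh.attrs["t_r"] = t_r
        g = fh.create_group("electrodes")
        for (r, c), tr in sorted(trains.items()):
            g.create_dataset(f"r{r:03d}c{c:03d}", data=tr.times)


def read_spikes_hdf5(path) -> tuple[dict, float, float]:
    with h5py.File(_require(path), "r") as fh:
        f_s = float(fh.attrs["f_s"])
        t_r = float(fh.attrs["t_r"])
        trains = {}
        for name, ds in fh["electrodes"].items():
            r, c = int(name[1:4]), int(name[5:8])
            trains[(r, c)] = SpikeTrain(r, c, np.asarray(ds), t_r)
    return trains, f_s, t_r


# ---------------------------------------------------------------------------
# neuron map
# ---------------------------------------------------------------------------

def write_neuron_map(path, neuron_map: dict):
    df = pd.DataFrame(
        [(r, c, n) for (r, c), n in sorted(neuron_map.items())],
        columns=["row", "col", "n_neurons"])
    df.to_csv(path, index=False)


def read_neuron_map(path) -> dict:
    df = pd.read_csv(_require(path))
    missing = {"row", "col", "n_neurons"} - set(df.columns)
    if missing:
        raise InputError(f"neuron map missing columns {sorted(missing)}")
    return {(int(r), int(c)): int(n)
            for r, c, n in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# graphs and link tables
# ---------------------------------------------------------------------------

def write_structural_edges(path, sc: StructuralGraph, grid):
    r, c = grid.node_rc(sc.seeds)
    a, b = sc.edges[:, 0], sc.edges[:, 1]
    df = pd.DataFrame({
        "row_a": r[a], "col_a": c[a], "row_b": r[b], "col_b": c[b],
        "strength": sc.strength[a, b], "euclid_um": sc.edge_length_um,
    })
    df.to_csv(path, index=False)
    return df


def write_distance_table(path, sc: StructuralGraph, grid):
    r, c = grid.node_rc(sc.seeds)
    iu = np.triu_indices(len(sc.seeds), k=1)
    df = pd.DataFrame({
        "row_a": r[iu[0]], "col_a": c[iu[0]],
        "row_b": r[iu[1]], "col_b": c[iu[1]],
        "d_um": sc.distance_um[iu], "d_norm": sc.distance_norm[iu],
        "reachable": sc.reachable[iu],
    })
    df.to_csv(path, index=False)
    return df


def functional_links_frame(links, entropies: dict | None = None) -> pd.DataFrame:
    rows = []
    for l in links:
        rows.append({
            "row_x": l.x[0], "col_x": l.x[1], "row_y": l.y[0], "col_y": l.y[1],
            "C_P": l.c_p,
            "C_tau_ms": np.nan if l.c_tau is None else l.c_tau * 1e3,
            "C_O": l.c_o,
            "C_H": (entropies or {}).get((l.x, l.y), np.nan),
            "euclid_um": l.euclid_um,
            "passed_velocity": l.survives_velocity_filter,
            "significant": l.significant_vs_cs,
        })
    return pd.DataFrame(rows)


def read_functional_links(path) -> list:
    df = pd.read_csv(_require(path))
    links = []
    for t in df.itertuples(index=False):
        links.append(FunctionalLink(
            x=(int(t.row_x), int(t.col_x)), y=(int(t.row_y), int(t.col_y)),
            c_p=float(t.C_P),
            c_tau=None if np.isnan(t.C_tau_ms) else float(t.C_tau_ms) / 1e3,
            c_o=int(t.C_O), euclid_um=float(t.euclid_um),
            survives_velocity_filter=bool(t.passed_velocity),
            significant_vs_cs=bool(t.significant)))
    return links


def refined_links_frame(links) -> pd.DataFrame:
    rows = []
    for l in links:
        rows.append({
            "row_x": l.x[0], "col_x": l.x[1], "row_y": l.y[0], "col_y": l.y[1],
            "C_P": l.c_p, "C_P_norm": l.c_p_norm,
            "d_um": l.d_um, "d_norm": l.d_norm, "reachable": l.reachable,
            "W": l.weight, "retained": l.significant_vs_ws,
        })
    return pd.DataFrame(rows)


def read_refined_links(path) -> list:
    df = pd.read_csv(_require(path))
    links = []
    for t in df.itertuples(index=False):
        links.append(RefinedLink(
            x=(int(t.row_x), int(t.col_x)), y=(int(t.row_y), int(t.col_y)),
            c_p=float(t.C_P), c_p_norm=float(t.C_P_norm), d_um=float(t.d_um),
            d_norm=float(t.d_norm), reachable=bool(t.reachable),
            weight=float(t.W), significant_vs_ws=bool(t.retained)))
    return links


def write_null_model(path_npz, null: NullModel):
    np.savez(path_npz,
             peaks=null.peaks,
             pairs=np.array([[a[0], a[1], b[0], b[1]] for a, b in null.pairs]),
             meta=np.array([null.c_s, null.jitter_s, null.reps, null.p_value,
                            -1 if null.seed is None else null.seed]))


def read_null_model(path_npz) -> NullModel:
    data = np.load(_require(path_npz))
    pairs = [((int(r1), int(c1)), (int(r2), int(c2)))
             for r1, c1, r2, c2 in data["pairs"]]
    c_s, jitter, reps, p, seed = data["meta"]
    return NullModel(pairs=pairs, peaks=data["peaks"], c_s=float(c_s),
                     jitter_s=float(jitter), reps=int(reps), p_value=float(p),
                     seed=None if seed < 0 else int(seed))


def null_summary_json(null: NullModel) -> dict:
    return {"C_s": null.c_s, "reps": null.reps, "seed": null.seed,
            "n_pairs": len(null.pairs), "jitter_ms": null.jitter_s * 1e3,
            "p_value": null.p_value}


def write_graphml(path, sc: StructuralGraph, grid):
    g = nx.Graph()
    r, c = grid.node_rc(sc.seeds)
    for i, s in enumerate(sc.seeds):
        g.add_node(int(s), row=int(r[i]), col=int(c[i]))
    for (a, b), length in zip(sc.edges, sc.edge_length_um):
        g.add_edge(int(sc.seeds[a]), int(sc.seeds[b]),
                   strength=float(sc.strength[a, b]), euclid_um=float(length))
    nx.write_graphml(g, path)


def write_features_npz(path, features: np.ndarray):
    """Directional features as an (n_rows, n_cols, 8) array; bin order is
    E, NE, N, NW, W, SW, S, SE (counterclockwise from the +x image axis)."""
    np.savez(path, features=features,
             bin_order=np.array(["E", "NE", "N", "NW", "W", "SW", "S", "SE"]))


def read_features_npz(path) -> np.ndarray:
    return np.load(_require(path))["features"]


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(_require(path).read_text())
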