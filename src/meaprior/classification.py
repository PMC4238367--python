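"""Characterization of retained vs discarded functional links.

Each link is described by features of its correlogram and firing
statistics: peak value C_P, raw coincidence count C_O, peak lag C_tau,
correlogram entropy C_H (spread of the normalized correlogram, in bits),
and the mean firing rates of the two electrodes.  A linear SVM under
stratified 10-fold cross-validation quantifies how well every non-empty
combination of the five feature groups separates the two classes; the
analytic noise level ACC_eta (majority-class accuracy) marks the plateau
of uninformative subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import ContractError, InputError
from .functional import peak as correlogram_peak

FEATURE_GROUPS = (
    ("C_P",),
    ("C_O",),
    ("C_tau_ms",),
    ("C_H",),
    ("MFR_x", "MFR_y"),
)
FEATURE_COLUMNS = tuple(c for g in FEATURE_GROUPS for c in g)


@dataclass
class ClassificationResult:
    table: pd.DataFrame  # one row per feature subset: groups, mean, std, rank
    acc_eta: float  # analytic noise level, percent
    folds: int
    seed: int


def correlogram_entropy(values: np.ndarray) -> float:
    """Shannon entropy (bits) of the correlogram normalized to unit mass.

    C_H = -sum C_n(tau) log2 C_n(tau) with C_n = C / sum(C); zero bins
    contribute nothing.  A single occupied bin gives 0; K equally occupied
    bins give log2(K).  Raises on an all-zero correlogram (undefined).
    """
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ContractError("entropy undefined for an all-zero correlogram")
    p = v[v > 0] / total
    return float(-(p * np.log2(p)).sum())


def extract_features(refined_links, correlograms: dict, trains: dict,
                     t_r: float) -> pd.DataFrame:
    """One feature row per labeled link.

    ``correlograms`` maps the unordered (x, y) pair to its Correlogram;
    ``trains`` maps (row, col) to the SpikeTrain.  C_O is cross-checked
    against the identity C_O = C_P * T * sqrt(MFR_x * MFR_y) (they agree
    up to the integer rounding of counts).
    """
    rows = []
    for link in refined_links:
        key = (link.x, link.y) if (link.x, link.y) in correlograms \
            else (link.y, link.x)
        if key not in correlograms:
            raise InputError(f"missing correlogram for link {link.x}-{link.y}")
        cg = correlograms[key]
        tx, ty = trains[link.x], trains[link.y]
        c_p, c_tau, c_o = correlogram_peak(cg)
        c_tau_ms = np.nan if c_tau is None else c_tau * 1e3
        rows.append({
            "row_x": link.x[0], "col_x": link.x[1],
            "row_y": link.y[0], "col_y": link.y[1],
            "C_P": c_p,
            "C_O": c_o,
            "C_tau_ms": c_tau_ms,
            "C_H": correlogram_entropy(cg.values) if cg.values.sum() > 0 else np.nan,
            "MFR_x": tx.n_spikes / t_r,
            "MFR_y": ty.n_spikes / t_r,
            "label": link.label,
        })
    df = pd.DataFrame(rows)
    if len(df):
        ident = df["C_P"] * t_r * np.sqrt(df["MFR_x"] * df["MFR_y"])
        if not np.allclose(df["C_O"], ident, atol=0.5 + 1e-9):
            raise ContractError("C_O does not match C_P * T * sqrt(MFR_x * MFR_y)")
    return df


def noise_level(n_retained: int, n_discarded: int) -> float:
    """Analytic accuracy (percent, one decimal) of the majority classifier."""
    total = n_retained + n_discarded
    if total <= 0:
        raise ContractError("class counts must be positive")
    return round(100.0 * max(n_retained, n_discarded) / total, 1)


def svm_feature_ranking(table: pd.DataFrame, folds: int = 10, seed: int = 0,
                        C: float = 1.0, subsets=None) -> ClassificationResult:
    """Linear-SVM accuracy of every feature-group subset under stratified CV.

    Features are standardized inside each training fold.  Subsets default
    to all non-empty combinations of the five feature groups (31 total)
    and are ranked by mean accuracy (percent).
    """
    df = table.dropna(subset=list(FEATURE_COLUMNS))
    y = df["label"].to_numpy()
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or class_counts.min() < 2:
        raise ContractError("need at least two examples of each class")
    if subsets is None:
        subsets = [
            sum(combo, ())
            for r in range(1, len(FEATURE_GROUPS) + 1)
            for combo in combinations(FEATURE_GROUPS, r)
        ]
    folds = min(folds, int(class_counts.min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for cols in subsets:
        X = df[list(cols)].to_numpy()
        clf = make_pipeline(StandardScaler(), LinearSVC(C=C))
        scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
        rows.append({"features": "+".join(cols),
                     "mean_accuracy_pct": 100.0 * scores.mean(),
                     "std_accuracy_pct": 100.0 * scores.std()})
    out = pd.DataFrame(rows).sort_values(
        "mean_accuracy_pct", ascending=False, kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    counts = {c: int(n) for c, n in zip(classes, class_counts)}
    acc_eta = noise_level(counts.get("retained", 0), counts.get("discarded", 0))
    return ClassificationResult(table=out, acc_eta=acc_eta, folds=folds, seed=seed)
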