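"""Per-ROI feature extraction: 42 features per ROI.

Each ROI of a subject contributes a 42-vector: 32 orthonormal Haar wavelet
coefficients (d3 16, d4 8, a4 8 — of the first 128 timepoints) followed by
the 10 graph measures of the subject's thresholded connectivity graph (8
node-level values at the ROI's node, plus the 2 graph-level values replicated
to every ROI).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .graphs import (
    GRAPH_FEATURE_NAMES,
    connectivity_matrix,
    global_graph_measures,
    local_graph_measures,
    threshold_graph,
)
from .wavelets import WAVELET_FEATURE_NAMES, hwt_features

__all__ = [
    "N_FEATURES",
    "FEATURE_NAMES",
    "FEATURE_NAME_MAP",
    "extract_roi_features",
    "extract_cohort_features",
    "write_feature_table",
    "read_feature_table",
    "feature_matrix",
]

#: Canonical feature names in vector order (wavelet bands, then graph
#: measures).
FEATURE_NAMES: list[str] = list(WAVELET_FEATURE_NAMES) + list(GRAPH_FEATURE_NAMES)
N_FEATURES: int = len(FEATURE_NAMES)  # 42

#: Column label (f01..f42) -> descriptive feature name.
FEATURE_NAME_MAP: dict[str, str] = {
    f"f{i + 1:02d}": name for i, name in enumerate(FEATURE_NAMES)
}


def extract_roi_features(
    subject: SubjectRecord,
    graph_density: float = 0.20,
    n_rewires: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Feature matrix of one subject: ``n_rois x 42``.

    The connectivity graph is built once per subject (absolute Pearson
    correlation, proportional thresholding at ``graph_density``); the two
    global measures are shared by all of the subject's ROIs.
    """
    series = subject.roi_series
    n_rois = series.shape[0]
    graph = threshold_graph(connectivity_matrix(series), graph_density)
    local = local_graph_measures(graph)
    glob = global_graph_measures(graph, n_rewires=n_rewires, seed=seed)
    out = np.empty((n_rois, N_FEATURES))
    for r in range(n_rois):
        out[r, :32] = hwt_features(series[r])
        out[r, 32:40] = local[r]
        out[r, 40] = glob.assortativity
        out[r, 41] = glob.small_worldness
    return out


def extract_cohort_features(
    subjects: Sequence[SubjectRecord],
    graph_density: float = 0.20,
    n_rewires: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format feature table: one row per (subject, ROI).

    Columns: subject_id, label, roi, f01..f42 (see ``FEATURE_NAME_MAP``).
    """
    frames = []
    for sub in subjects:
        feats = extract_roi_features(sub, graph_density, n_rewires, seed)
        df = pd.DataFrame(feats, columns=list(FEATURE_NAME_MAP))
        df.insert(0, "roi", np.arange(feats.shape[0]))
        df.insert(0, "label", sub.label)
        df.insert(0, "subject_id", sub.subject_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"subject_id", "label", "roi", *FEATURE_NAME_MAP} - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return df


def feature_matrix(table: pd.DataFrame, roi: int) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One ROI's 42-column matrix across subjects.

    Returns (X, labels, subject_ids) with rows ordered by subject_id.
    """
    sub = table[table["roi"] == roi].sort_values("subject_id")
    x = sub[list(FEATURE_NAME_MAP)].to_numpy(dtype=float)
    return x, sub["label"].to_numpy(), sub["subject_id"].tolist()
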