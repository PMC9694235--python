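"""Orthonormal Haar wavelet analysis of ROI time series.

Convention: one analysis step maps adjacent pairs (x1, x2) to an
approximation a = (x1 + x2)/sqrt(2) and a detail d = (x1 - x2)/sqrt(2); the
step recurses on the approximations.  The transform is orthonormal, so total
energy is conserved (Parseval).
"""

from __future__ import annotations

import numpy as np

__all__ = ["haar_transform", "hwt_features", "average_of_voxels", "WAVELET_FEATURE_NAMES"]

_SQRT2 = np.sqrt(2.0)

#: Names of the 32 wavelet features, in output order.
WAVELET_FEATURE_NAMES: list[str] = (
    [f"d3_{i:02d}" for i in range(16)]
    + [f"d4_{i:02d}" for i in range(8)]
    + [f"a4_{i:02d}" for i in range(8)]
)


def average_of_voxels(voxel_series_set: np.ndarray) -> np.ndarray:
    """Per-timepoint arithmetic mean over a set of voxel series.

    ``voxel_series_set`` is an ``n_voxels x n_timepoints`` array (or a
    sequence of equal-length 1-D series); the mean is the ROI's
    representative signal.
    """
    arr = np.asarray(voxel_series_set, dtype=float)
    if arr.ndim == 1:
        raise ValueError("expected a set of voxel series, got a single 1-D series")
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("voxel series set must be a non-empty 2-D array")
    return arr.mean(axis=0)


def haar_transform(series: np.ndarray, levels: int) -> dict[str, np.ndarray]:
    """Multi-level orthonormal Haar analysis.

    Returns a dict with detail coefficients ``d1 .. d<levels>`` and the final
    approximation ``a<levels>``.  The input length must be divisible by
    ``2**levels``; callers truncate or pad beforehand.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if x.size % (1 << levels) != 0:
        raise ValueError(
            f"series length {x.size} not divisible by 2^{levels} = {1 << levels}"
        )
    out: dict[str, np.ndarray] = {}
    approx = x
    for lev in range(1, levels + 1):
        pairs = approx.reshape(-1, 2)
        out[f"d{lev}"] = (pairs[:, 0] - pairs[:, 1]) / _SQRT2
        approx = (pairs[:, 0] + pairs[:, 1]) / _SQRT2
    out[f"a{levels}"] = approx
    return out


def hwt_features(series: np.ndarray) -> np.ndarray:
    """The 32 Haar features of one ROI series: d3 (16) ++ d4 (8) ++ a4 (8).

    The series is truncated to its first 128 samples (the largest power of
    two inside a 140-point acquisition) and analysed to level 4.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size < 128:
        raise ValueError(f"series length {x.size} < 128")
    coeffs = haar_transform(x[:128], levels=4)
    return np.concatenate([coeffs["d3"], coeffs["d4"], coeffs["a4"]])
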