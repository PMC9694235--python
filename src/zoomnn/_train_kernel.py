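"""Compiled inner loop for neuro-fuzzy training.

The update rule is sequential over instances (each winner update changes the
membership landscape the next instance sees), so it cannot be vectorised;
this kernel keeps the many small per-instance updates fast.  Semantics are
pinned by the pure-step reference oracle in the test suite: winner-take-all
on raw memberships (ties to the lowest MF index), center moved toward the
value and clamped between its neighbours, weights stepped and clipped to
[0, 1], supports implied by the neighbour-center rule, early stop on
training-accuracy patience.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["train_inplace"]


@njit(cache=True)
def _mu(x: float, crow, j: int, m: int, halfwidth: float) -> float:
    """Triangular membership of MF ``j`` (support endpoints at the adjacent
    centers, outermost supports extrapolated by one gap)."""
    if m == 1:
        left = crow[0] - halfwidth
        right = crow[0] + halfwidth
    else:
        left = crow[j - 1] if j > 0 else crow[0] - (crow[1] - crow[0])
        right = crow[j + 1] if j < m - 1 else crow[m - 1] + (crow[m - 1] - crow[m - 2])
    c = crow[j]
    if x < left or x > right:
        return 0.0
    rise = 1.0 if c <= left else (x - left) / (c - left)
    fall = 1.0 if right <= c else (right - x) / (right - c)
    v = rise if rise < fall else fall
    if v < 0.0:
        return 0.0
    if v > 1.0:
        return 1.0
    return v


@njit(cache=True)
def _accuracy(X, y, centers, weights, halfwidth) -> float:
    n, f = X.shape
    m = centers.shape[2]
    correct = 0
    for i in range(n):
        s0 = 0.0
        s1 = 0.0
        for q in range(f):
            for cls in range(2):
                b = 0.0
                for j in range(m):
                    b += weights[q, cls, j] * _mu(X[i, q], centers[q, cls], j, m, halfwidth[q])
                if b > 1.0:
                    b = 1.0
                if cls == 0:
                    s0 += b
                else:
                    s1 += b
        pred = 1 if s1 > s0 else 0  # tie -> class 0
        if pred == y[i]:
            correct += 1
    return correct / n


@njit(cache=True)
def train_inplace(X, y, centers, weights, halfwidth,
                  alpha: float, delta: float, max_epochs: int, patience: int) -> int:
    """Run the feedforward update rule in place; returns epochs executed."""
    n, f = X.shape
    m = centers.shape[2]
    best = -1.0
    stall = 0
    epochs = 0
    for _ in range(max_epochs):
        for i in range(n):
            label = y[i]
            opp = 1 - label
            for q in range(f):
                x = X[i, q]
                wt = 0
                bt = -1.0
                for j in range(m):
                    v = _mu(x, centers[q, label], j, m, halfwidth[q])
                    if v > bt:
                        bt = v
                        wt = j
                wo = 0
                bo = -1.0
                for j in range(m):
                    v = _mu(x, centers[q, opp], j, m, halfwidth[q])
                    if v > bo:
                        bo = v
                        wo = j
                c = centers[q, label, wt]
                cn = c + alpha * (x - c)
                if m > 1:
                    if wt > 0 and cn < centers[q, label, wt - 1]:
                        cn = centers[q, label, wt - 1]
                    if wt < m - 1 and cn > centers[q, label, wt + 1]:
                        cn = centers[q, label, wt + 1]
                centers[q, label, wt] = cn
                w = weights[q, label, wt] + delta
                weights[q, label, wt] = 1.0 if w > 1.0 else w
                w = weights[q, opp, wo] - delta
                weights[q, opp, wo] = 0.0 if w < 0.0 else w
        epochs += 1
        acc = _accuracy(X, y, centers, weights, halfwidth)
        if acc > best:
            best = acc
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    return epochs
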