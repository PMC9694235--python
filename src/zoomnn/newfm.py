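"""Neuro-fuzzy base learner with weighted fuzzy membership functions.

The model keeps, for every (feature, class) pair, a small bank of triangular
membership functions (MFs).  A class's activation on a feature value is the
*bounded sum* of the weighted memberships, capped at 1 (a BSWFM curve).
Classification sums the per-feature class activations over the selected
features; a scalar score in [0, 1] is produced by Takagi-Sugeno style
defuzzification of the class contrast.

Training is feedforward and deterministic: for each instance and feature, the
most-activated MF of the true class moves its vertex toward the observed
value and gains weight, while the most-activated MF of the opposite class
loses weight.  There is no gradient and no backpropagation.

Feature selection ranks features by the non-overlap area between the two
classes' BSWFM curves — a feature whose fuzzy class profiles coincide carries
no information and ranks last.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from ._train_kernel import train_inplace

__all__ = ["NEWFM"]

_FORMAT = "newfm-1"


class NEWFM:
    """Binary neuro-fuzzy classifier (classes 0 and 1).

    Parameters
    ----------
    n_mfs
        Membership functions per (feature, class); centers start evenly
        spaced across the training range of the feature.
    learning_rate
        Fraction of the (value - center) gap the winning MF's center moves
        per update.
    weight_delta
        Weight increment/decrement per update, clipped to [0, 1].
    max_epochs
        Upper bound on training sweeps over the data.
    patience
        Training stops once training accuracy has not improved for this many
        consecutive epochs.
    n_select
        If set, keep only the top ``n_select`` features (by BSWFM
        non-overlap area) for classification after training.
    """

    def __init__(
        self,
        n_mfs: int = 3,
        learning_rate: float = 0.1,
        weight_delta: float = 0.1,
        max_epochs: int = 50,
        patience: int = 3,
        n_select: int | None = None,
    ) -> None:
        if n_mfs < 1:
            raise ValueError("n_mfs must be >= 1")
        if not 0 < learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if not 0 < weight_delta <= 1:
            raise ValueError("weight_delta must lie in (0, 1]")
        self.n_mfs = n_mfs
        self.learning_rate = learning_rate
        self.weight_delta = weight_delta
        self.max_epochs = max_epochs
        self.patience = patience
        self.n_select = n_select
        self.n_features_: int | None = None

    # -- structure ---------------------------------------------------------

    @classmethod
    def from_ranges(cls, ranges: Sequence[tuple[float, float]], **hyper) -> "NEWFM":
        """Untrained model with MF banks laid out over explicit feature ranges."""
        model = cls(**hyper)
        model._init_structure(np.asarray(ranges, dtype=float))
        return model

    def _init_structure(self, ranges: np.ndarray) -> None:
        if ranges.ndim != 2 or ranges.shape[1] != 2:
            raise ValueError("ranges must be (n_features, 2)")
        n_f = ranges.shape[0]
        if n_f == 0:
            raise ValueError("need at least one feature")
        if not np.all(np.isfinite(ranges)):
            raise ValueError("ranges must be finite")
        lo, hi = ranges[:, 0].copy(), ranges[:, 1].copy()
        degenerate = hi <= lo
        if degenerate.any():
            # widen zero-width ranges by a machine-epsilon-scaled pad
            pad = np.maximum(np.abs(lo), 1.0) * 1e-9
            lo = np.where(degenerate, lo - pad, lo)
            hi = np.where(degenerate, hi + pad, hi)
        self.degenerate_ranges_ = np.nonzero(degenerate)[0].tolist()
        self.ranges_ = np.column_stack([lo, hi])
        self.n_features_ = n_f
        m = self.n_mfs
        if m == 1:
            grid = (lo + hi)[:, None] / 2.0
        else:
            grid = lo[:, None] + (hi - lo)[:, None] * np.arange(m) / (m - 1)
        self.centers_ = np.repeat(grid[:, None, :], 2, axis=1)  # (f, 2, m)
        self.weights_ = np.zeros_like(self.centers_)
        self.selected_ = list(range(n_f))
        self._refresh_supports()

    def _refresh_supports(self) -> None:
        """Support endpoints from the current centers (neighbor-center rule).

        Each MF's support reaches the adjacent MF centers; the outermost
        supports extrapolate by one inter-center gap.  Centers are kept
        ordered during training, so left <= center <= right always holds.
        """
        c = self.centers_
        m = self.n_mfs
        if m == 1:
            half = (self.ranges_[:, 1] - self.ranges_[:, 0])[:, None, None]
            self.lefts_ = c - half
            self.rights_ = c + half
            return
        lefts = np.empty_like(c)
        rights = np.empty_like(c)
        lefts[..., 1:] = c[..., :-1]
        lefts[..., 0] = c[..., 0] - (c[..., 1] - c[..., 0])
        rights[..., :-1] = c[..., 1:]
        rights[..., -1] = c[..., -1] + (c[..., -1] - c[..., -2])
        self.lefts_, self.rights_ = lefts, rights

    # -- evaluation --------------------------------------------------------

    def _check_fitted(self) -> None:
        if self.n_features_ is None:
            raise ValueError("model has no structure; fit it or use from_ranges")

    def _as_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_:
            raise ValueError(f"expected {self.n_features_} features, got {X.shape[1]}")
        return X

    def _mf_memberships(self, X: np.ndarray) -> np.ndarray:
        """Raw triangular memberships, shape (n, f, 2, m)."""
        x = X[:, :, None, None]
        l, c, r = self.lefts_, self.centers_, self.rights_
        with np.errstate(divide="ignore", invalid="ignore"):
            rise = (x - l) / (c - l)
            fall = (r - x) / (r - c)
        rise = np.where(c > l, rise, 1.0)
        fall = np.where(r > c, fall, 1.0)
        mu = np.clip(np.minimum(rise, fall), 0.0, 1.0)
        return np.where((x < l) | (x > r), 0.0, mu)

    def bswfm(self, X: np.ndarray) -> np.ndarray:
        """Bounded-sum class activations, shape (n, f, 2), values in [0, 1]."""
        self._check_fitted()
        X = self._as_matrix(X)
        mu = self._mf_memberships(X)
        return np.minimum(1.0, (self.weights_ * mu).sum(axis=-1))

    def _scores(self, X: np.ndarray, selected: Sequence[int] | None = None) -> np.ndarray:
        b = self.bswfm(X)
        sel = list(self.selected_) if selected is None else list(selected)
        return b[:, sel, :].sum(axis=1)  # (n, 2)

    def predict(self, X: np.ndarray, selected: Sequence[int] | None = None) -> np.ndarray:
        """Class labels; ties go to class 0."""
        s = self._scores(X, selected)
        return (s[:, 1] > s[:, 0]).astype(int)

    def tsd(self, X: np.ndarray) -> np.ndarray:
        """Defuzzified class score in [0, 1]; 0.5 is the decision point.

        T = sum(b1 - b0) / sum(b1 + b0) over selected features, mapped to
        (T + 1) / 2; an all-zero denominator maps to 0.5.
        """
        b = self.bswfm(X)[:, self.selected_, :]
        num = (b[:, :, 1] - b[:, :, 0]).sum(axis=1)
        den = (b[:, :, 1] + b[:, :, 0]).sum(axis=1)
        t = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        return (t + 1.0) / 2.0

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, max_epochs: int | None = None) -> "NEWFM":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the number of instances")
        if X.shape[0] == 0:
            raise ValueError("no instances")
        classes = set(y.tolist())
        if not classes <= {0, 1}:
            raise ValueError("labels must be 0/1")
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        ranges = np.column_stack([X.min(axis=0), X.max(axis=0)])
        self._init_structure(ranges)

        epochs = self.max_epochs if max_epochs is None else max_epochs
        halfwidth = np.ascontiguousarray(self.ranges_[:, 1] - self.ranges_[:, 0])
        self.epochs_run_ = int(
            train_inplace(
                np.ascontiguousarray(X),
                np.ascontiguousarray(y),
                self.centers_,
                self.weights_,
                halfwidth,
                self.learning_rate,
                self.weight_delta,
                epochs,
                self.patience,
            )
        )
        self._refresh_supports()

        self.feature_importances_ = self._non_overlap_areas()
        if self.n_select is not None:
            self.selected_ = self.select_features(self.n_select)
        self.train_accuracy_ = float((self.predict(X) == y).mean())
        return self

    # -- feature selection --------------------------------------------------

    def _non_overlap_areas(self, n_grid: int = 256) -> np.ndarray:
        """Per-feature integral of |BSWFM_1(x) - BSWFM_0(x)| over the range."""
        self._check_fitted()
        areas = np.empty(self.n_features_)
        for i in range(self.n_features_):
            lo, hi = self.ranges_[i]
            grid = np.linspace(lo, hi, n_grid)
            x = grid[:, None, None, None]
            l = self.lefts_[i][None]
            c = self.centers_[i][None]
            r = self.rights_[i][None]
            with np.errstate(divide="ignore", invalid="ignore"):
                rise = (x - l) / (c - l)
                fall = (r - x) / (r - c)
            rise = np.where(c > l, rise, 1.0)
            fall = np.where(r > c, fall, 1.0)
            mu = np.clip(np.minimum(rise, fall), 0.0, 1.0)
            mu = np.where((x < l) | (x > r), 0.0, mu)[:, 0]
            b = np.minimum(1.0, (self.weights_[i][None] * mu).sum(axis=-1))  # (g, 2)
            areas[i] = np.trapezoid(np.abs(b[:, 1] - b[:, 0]), grid)
        return areas

    def select_features(self, n_keep: int) -> list[int]:
        """Top ``n_keep`` features by non-overlap area, ties to lower index."""
        self._check_fitted()
        if not 1 <= n_keep <= self.n_features_:
            raise ValueError(f"n_keep must lie in [1, {self.n_features_}]")
        areas = getattr(self, "feature_importances_", None)
        if areas is None:
            areas = self._non_overlap_areas()
        order = sorted(range(self.n_features_), key=lambda i: (-areas[i], i))
        return order[:n_keep]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "format": _FORMAT,
            "hyperparams": {
                "n_mfs": self.n_mfs,
                "learning_rate": self.learning_rate,
                "weight_delta": self.weight_delta,
                "max_epochs": self.max_epochs,
                "patience": self.patience,
                "n_select": self.n_select,
            },
            "ranges": self.ranges_.tolist(),
            "centers": self.centers_.tolist(),
            "weights": self.weights_.tolist(),
            "selected": list(self.selected_),
            "degenerate_ranges": list(getattr(self, "degenerate_ranges_", [])),
            "train_accuracy": getattr(self, "train_accuracy_", None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NEWFM":
        if d.get("format") != _FORMAT:
            raise ValueError(f"unsupported model format: {d.get('format')!r}")
        model = cls(**d["hyperparams"])
        model.ranges_ = np.asarray(d["ranges"], dtype=float)
        model.n_features_ = model.ranges_.shape[0]
        model.centers_ = np.asarray(d["centers"], dtype=float)
        model.weights_ = np.asarray(d["weights"], dtype=float)
        model.selected_ = list(d["selected"])
        model.degenerate_ranges_ = list(d.get("degenerate_ranges", []))
        if d.get("train_accuracy") is not None:
            model.train_accuracy_ = d["train_accuracy"]
        model._refresh_supports()
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NEWFM":
        return cls.from_dict(json.loads(Path(path).read_text()))
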