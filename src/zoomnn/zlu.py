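"""Zoom-in learning unit (ZLU).

A ZLU wraps three neuro-fuzzy learners over one block of input features:

* *standard* — trained on all instances of the block;
* *subpattern* — trained on the instances the standard model misclassifies
  (MIs), to capture a secondary pattern the standard fit ignored;
* *refined* — trained on the correctly classified instances (CCIs), a
  noise-reduced subset of the main pattern.

At test time only the subpattern and refined models are consulted; the unit
emits their two defuzzified scores (t_m, t_c) for the next layer.  When a
group is too small or single-class, the corresponding component falls back to
a copy of the standard model so the unit's outputs are always defined.
"""

from __future__ import annotations

import numpy as np

from .newfm import NEWFM

__all__ = ["ZLU", "instance_grouping"]

_FORMAT = "zlu-1"


def instance_grouping(model: NEWFM, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split instance indices into (misclassified, correctly classified).

    The two index arrays partition ``range(len(y))``.
    """
    pred = model.predict(X)
    y = np.asarray(y, dtype=int)
    wrong = pred != y
    return np.nonzero(wrong)[0], np.nonzero(~wrong)[0]


class ZLU:
    """One zoom-in learning unit.

    Parameters
    ----------
    min_count
        Smallest instance-group size worth fitting a dedicated model on;
        below it (or when a group is single-class) the component falls back
        to a copy of the standard model.
    n_select
        Optional feature selection during standard training; the selected
        subset is shared with the subpattern and refined models unless
        ``independent_selection`` is set.
    newfm_params
        Hyperparameters forwarded to the three inner learners.
    """

    def __init__(
        self,
        min_count: int = 4,
        n_select: int | None = None,
        independent_selection: bool = False,
        newfm_params: dict | None = None,
    ) -> None:
        self.min_count = min_count
        self.n_select = n_select
        self.independent_selection = independent_selection
        self.newfm_params = dict(newfm_params or {})

    def _new(self, n_select: int | None) -> NEWFM:
        return NEWFM(n_select=n_select, **self.newfm_params)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ZLU":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        if len(set(y.tolist())) < 2:
            raise ValueError("ZLU training needs both classes")
        self.standard_ = self._new(self.n_select).fit(X, y)
        mi, cci = instance_grouping(self.standard_, X, y)
        self.mi_indices_, self.cci_indices_ = mi, cci

        if self.n_select is None:
            shared_cols = None
        elif self.independent_selection:
            shared_cols = None  # components run their own selection
        else:
            shared_cols = list(self.standard_.selected_)
        comp_select = None if shared_cols is not None else (
            self.n_select if self.independent_selection else None
        )

        def build(idx: np.ndarray) -> tuple[NEWFM, bool, list[int] | None]:
            usable = idx.size >= self.min_count and len(set(y[idx].tolist())) == 2
            if not usable:
                return NEWFM.from_dict(self.standard_.to_dict()), True, None
            cols = shared_cols
            Xs = X[idx] if cols is None else X[np.ix_(idx, cols)]
            return self._new(comp_select).fit(Xs, y[idx]), False, cols

        self.subpattern_, self.subpattern_fallback_, self._sub_cols = build(mi)
        self.refined_, self.refined_fallback_, self._ref_cols = build(cci)
        return self

    def _component_tsd(self, comp: NEWFM, cols: list[int] | None, X: np.ndarray) -> np.ndarray:
        return comp.tsd(X if cols is None else X[:, cols])

    def tsd_pair(self, X: np.ndarray) -> np.ndarray:
        """Zoom-in output (t_m, t_c) per instance, shape (n, 2), values in [0, 1].

        Only the subpattern and refined models are evaluated; the standard
        model is not consulted (fallback components are value copies of it).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        t_m = self._component_tsd(self.subpattern_, self._sub_cols, X)
        t_c = self._component_tsd(self.refined_, self._ref_cols, X)
        return np.column_stack([t_m, t_c])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": _FORMAT,
            "params": {
                "min_count": self.min_count,
                "n_select": self.n_select,
                "independent_selection": self.independent_selection,
                "newfm_params": self.newfm_params,
            },
            "standard": self.standard_.to_dict(),
            "subpattern": self.subpattern_.to_dict(),
            "refined": self.refined_.to_dict(),
            "subpattern_fallback": self.subpattern_fallback_,
            "refined_fallback": self.refined_fallback_,
            "sub_cols": self._sub_cols,
            "ref_cols": self._ref_cols,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZLU":
        if d.get("format") != _FORMAT:
            raise ValueError(f"unsupported model format: {d.get('format')!r}")
        unit = cls(**d["params"])
        unit.standard_ = NEWFM.from_dict(d["standard"])
        unit.subpattern_ = NEWFM.from_dict(d["subpattern"])
        unit.refined_ = NEWFM.from_dict(d["refined"])
        unit.subpattern_fallback_ = d["subpattern_fallback"]
        unit.refined_fallback_ = d["refined_fallback"]
        unit._sub_cols = d["sub_cols"]
        unit._ref_cols = d["ref_cols"]
        return unit
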