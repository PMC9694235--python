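"""Zoom-in neural network (ZNN): stacked ZLU layers, trained feedforward.

The input feature vector is split into contiguous equal blocks, one per ZLU
of the first layer.  Each ZLU emits a pair of defuzzified scores for *every*
instance; the concatenation (t_m, t_c of unit 1, then unit 2, ...) is split
again into the next layer's input blocks.  A final neuro-fuzzy learner reads
the last layer's score vector and makes the decision.  Every stage is a
supervised feedforward fit — there is no gradient and no backpropagation.

Dimension contract: the first layer's unit count must divide the input
length, and each subsequent count must divide twice the previous count
(every unit emits two scores).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .newfm import NEWFM
from .zlu import ZLU

__all__ = ["ZNN", "split_features", "validate_layer_config"]

_FORMAT = "znn-1"


def split_features(values: np.ndarray, k: int) -> list[np.ndarray]:
    """Split the last axis of ``values`` into ``k`` contiguous equal blocks."""
    values = np.asarray(values)
    n = values.shape[-1]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n % k != 0:
        raise ValueError(f"cannot split {n} features into {k} equal blocks")
    return [b for b in np.split(values, k, axis=-1)]


def validate_layer_config(n_features: int, zlu_counts: Sequence[int]) -> None:
    """Check the divisibility contract before any training happens."""
    if not zlu_counts:
        raise ValueError("need at least one ZLU layer")
    if any(k < 1 for k in zlu_counts):
        raise ValueError("ZLU counts must be positive")
    if n_features % zlu_counts[0] != 0:
        raise ValueError(
            f"input length {n_features} not divisible by first-layer "
            f"ZLU count {zlu_counts[0]}"
        )
    for a, b in zip(zlu_counts, zlu_counts[1:]):
        if (2 * a) % b != 0:
            raise ValueError(
                f"layer emits {2 * a} scores, not divisible by next-layer "
                f"ZLU count {b}"
            )


class ZNN:
    """Stacked zoom-in network with a neuro-fuzzy output layer.

    Parameters
    ----------
    zlu_counts
        Units per ZLU layer, e.g. ``(16, 4)``.
    newfm_params
        Hyperparameters for every inner learner (ZLU components and the
        output layer).
    zlu_params
        Extra ZLU options (``min_count``, ``n_select``, ...); may be a single
        dict or one dict per layer for per-layer overrides.
    """

    def __init__(
        self,
        zlu_counts: Sequence[int] = (16, 4),
        newfm_params: dict | None = None,
        zlu_params: dict | Sequence[dict] | None = None,
    ) -> None:
        self.zlu_counts = tuple(int(k) for k in zlu_counts)
        self.newfm_params = dict(newfm_params or {})
        if zlu_params is None or isinstance(zlu_params, dict):
            self.zlu_params = [dict(zlu_params or {})] * len(self.zlu_counts)
        else:
            if len(zlu_params) != len(self.zlu_counts):
                raise ValueError("need one zlu_params dict per layer")
            self.zlu_params = [dict(p) for p in zlu_params]

    def _make_zlu(self, layer: int) -> ZLU:
        params = dict(self.zlu_params[layer])
        params.setdefault("newfm_params", self.newfm_params)
        return ZLU(**params)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ZNN":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        validate_layer_config(X.shape[1], self.zlu_counts)
        self.n_features_ = X.shape[1]

        current = X
        self.layers_: list[list[ZLU]] = []
        for li, k in enumerate(self.zlu_counts):
            blocks = split_features(current, k)
            layer = [self._make_zlu(li).fit(b, y) for b in blocks]
            self.layers_.append(layer)
            current = np.hstack([unit.tsd_pair(b) for unit, b in zip(layer, blocks)])
        self.output_ = NEWFM(**self.newfm_params).fit(current, y)
        self.train_accuracy_ = float((self.output_.predict(current) == y).mean())
        return self

    # -- forward pass (zoom-in test path only) ------------------------------

    def transform(self, X: np.ndarray) -> list[np.ndarray]:
        """Score matrices emitted by each ZLU layer, in order."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_:
            raise ValueError(f"expected {self.n_features_} features, got {X.shape[1]}")
        outputs = []
        current = X
        for layer in self.layers_:
            blocks = split_features(current, len(layer))
            current = np.hstack([unit.tsd_pair(b) for unit, b in zip(layer, blocks)])
            outputs.append(current)
        return outputs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.output_.predict(self.transform(X)[-1])

    def tsd(self, X: np.ndarray) -> np.ndarray:
        """Final defuzzified score in [0, 1] per instance."""
        return self.output_.tsd(self.transform(X)[-1])

    # -- layerwise readout ---------------------------------------------------

    def layerwise_accuracies(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_test: np.ndarray | None = None,
        y_test: np.ndarray | None = None,
    ) -> list[dict]:
        """Accuracy (%) attributable to each layer's representation.

        A ZLU layer is scored by the mean accuracy of its units: per unit, an
        auxiliary learner (an evaluation device, not part of the model) is
        trained on that unit's training score pair alone.  A first-layer unit
        sees a single feature block, so early layers score low; deeper layers
        aggregate more of the input and score higher.  The last entry is the
        fitted output layer itself, so it equals the model's accuracy.
        Returns one dict per ZLU layer plus the output layer.
        """
        y_train = np.asarray(y_train, dtype=int)
        train_layers = self.transform(X_train)
        test_layers = self.transform(X_test) if X_test is not None else None
        if y_test is not None:
            y_test = np.asarray(y_test, dtype=int)

        out = []
        for li, layer in enumerate(self.layers_):
            k = len(layer)
            pairs_tr = split_features(train_layers[li], k)
            pairs_te = split_features(test_layers[li], k) if test_layers is not None else [None] * k
            acc_tr, acc_te = [], []
            for p_tr, p_te in zip(pairs_tr, pairs_te):
                aux = NEWFM(**self.newfm_params).fit(p_tr, y_train)
                acc_tr.append(float((aux.predict(p_tr) == y_train).mean()))
                if p_te is not None:
                    acc_te.append(float((aux.predict(p_te) == y_test).mean()))
            entry = {"layer": f"zlu_layer_{li + 1}", "train": 100.0 * float(np.mean(acc_tr))}
            if acc_te:
                entry["test"] = 100.0 * float(np.mean(acc_te))
            out.append(entry)

        entry = {
            "layer": "output_layer",
            "train": 100.0 * float((self.output_.predict(train_layers[-1]) == y_train).mean()),
        }
        if test_layers is not None:
            pred = self.output_.predict(test_layers[-1])
            entry["test"] = 100.0 * float((pred == y_test).mean())
        out.append(entry)
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": _FORMAT,
            "zlu_counts": list(self.zlu_counts),
            "newfm_params": self.newfm_params,
            "zlu_params": self.zlu_params,
            "n_features": self.n_features_,
            "layers": [[unit.to_dict() for unit in layer] for layer in self.layers_],
            "output": self.output_.to_dict(),
            "train_accuracy": self.train_accuracy_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZNN":
        if d.get("format") != _FORMAT:
            raise ValueError(f"unsupported model format: {d.get('format')!r}")
        model = cls(d["zlu_counts"], d["newfm_params"], d["zlu_params"])
        model.n_features_ = d["n_features"]
        model.layers_ = [[ZLU.from_dict(u) for u in layer] for layer in d["layers"]]
        model.output_ = NEWFM.from_dict(d["output"])
        model.train_accuracy_ = d["train_accuracy"]
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ZNN":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise ValueError(f"corrupted model file {path}: {e}") from e
        return cls.from_dict(d)
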