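"""Experimental protocol: hold-out split, per-ROI ranking, region selection,
and end-to-end assessment of the three one-vs-rest diagnostic tasks.

The three binary tasks pit one class against the other two pooled:
AD vs NC+MCI (``A-NM``), NC vs AD+MCI (``N-AM``) and MCI vs AD+NC
(``M-AN``).  For each task, every ROI gets its own neuro-fuzzy learner on
its 42 features; ROIs are ranked by cross-validated training accuracy, the
best ``k`` ROIs (each reduced to its 20 most discriminative features) form
the network input, and a ZNN is trained and scored layer by layer.  Nothing
downstream of the split ever reads a test label.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .features import FEATURE_NAME_MAP, extract_cohort_features, feature_matrix
from .newfm import NEWFM
from .znn import ZNN

__all__ = [
    "TaskSpec",
    "TASKS",
    "HoldoutSplit",
    "RoiRanking",
    "EvaluationReport",
    "make_holdout",
    "rank_rois",
    "select_top_rois",
    "assemble_network_input",
    "run_assessment",
    "roi_overlap",
    "DISCRIMINATIVE_ROIS",
]


@dataclasses.dataclass(frozen=True)
class TaskSpec:
    """One binary one-vs-rest assessment."""

    name: str
    positive_class: str

    def binarize(self, labels: Sequence[str]) -> np.ndarray:
        return np.asarray([1 if lab == self.positive_class else 0 for lab in labels])


#: The three assessments; the negative class pools the two remaining labels.
TASKS: dict[str, TaskSpec] = {
    "A-NM": TaskSpec("A-NM", "AD"),
    "N-AM": TaskSpec("N-AM", "NC"),
    "M-AN": TaskSpec("M-AN", "MCI"),
}

#: Published top-16 discriminative AAL-90 regions per assessment, by accuracy
#: rank, as reported for the reference ADNI cohort.  Intersecting the three
#: columns gives the seven regions implicated across all assessments.
DISCRIMINATIVE_ROIS: dict[str, list[str]] = {
    "A-NM": [
        "cingulum_mid_r", "caudate_r", "caudate_l", "parietal_sup_l",
        "frontal_mid_r", "parietal_inf_l", "frontal_mid_l", "cuneus_r",
        "postcentral_r", "cuneus_l", "frontal_inf_oper_r", "frontal_inf_tri_r",
        "temporal_inf_r", "parietal_sup_r", "cingulum_mid_l",
        "frontal_sup_medial_r",
    ],
    "N-AM": [
        "cingulum_mid_r", "caudate_r", "amygdala_l", "frontal_sup_orb_l",
        "caudate_l", "parietal_sup_l", "lingual_l", "parahippocampal_l",
        "frontal_mid_r", "parietal_inf_l", "thalamus_l", "frontal_inf_oper_l",
        "frontal_mid_l", "cuneus_r", "insula_l", "postcentral_r",
    ],
    "M-AN": [
        "cingulum_mid_r", "postcentral_l", "caudate_l", "parietal_sup_l",
        "frontal_mid_r", "parietal_inf_l", "frontal_mid_l", "lingual_l",
        "postcentral_r", "cuneus_l", "frontal_inf_oper_r", "frontal_inf_tri_r",
        "temporal_inf_r", "parietal_sup_r", "cingulum_mid_l", "thalamus_l",
    ],
}


# ---------------------------------------------------------------------------
# hold-out split

@dataclasses.dataclass(frozen=True)
class HoldoutSplit:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")

    def to_dict(self) -> dict:
        return {
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HoldoutSplit":
        return cls(tuple(d["train_ids"]), tuple(d["test_ids"]), int(d["seed"]))


def make_holdout(
    subject_ids: Sequence[str],
    labels: Sequence[str],
    n_train_per_class: int = 23,
    seed: int = 0,
) -> HoldoutSplit:
    """Seeded per-class sampling of ``n_train_per_class`` training subjects.

    Everything not sampled goes to the test set; with the reference cohort
    sizes 34/89/45 the test set is 11 AD, 66 MCI and 22 NC subjects.
    """
    ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    for cls in sorted(set(labels.tolist())):
        members = np.sort(ids[labels == cls])
        if members.size < n_train_per_class:
            raise ValueError(
                f"class {cls!r} has {members.size} subjects, "
                f"needs >= {n_train_per_class}"
            )
        chosen = rng.choice(members, size=n_train_per_class, replace=False)
        train.extend(chosen.tolist())
    train_set = set(train)
    test = [s for s in ids.tolist() if s not in train_set]
    return HoldoutSplit(tuple(sorted(train)), tuple(sorted(test)), seed)


# ---------------------------------------------------------------------------
# per-ROI ranking

def _stratified_kfold(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold indices (deterministic, no external deps)."""
    rng = np.random.default_rng(seed)
    fold_of = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(idx.size) % k
    folds = []
    for f in range(k):
        test = np.nonzero(fold_of == f)[0]
        train = np.nonzero(fold_of != f)[0]
        folds.append((train, test))
    return folds


@dataclasses.dataclass(frozen=True)
class RoiRanking:
    """Per-ROI accuracy ranking with each ROI's selected feature indices."""

    entries: tuple[tuple[int, float, tuple[int, ...]], ...]  # (roi, acc %, features)

    def rois(self) -> list[int]:
        return [roi for roi, _, _ in self.entries]

    def selected_features(self, roi: int) -> list[int]:
        for r, _, feats in self.entries:
            if r == roi:
                return list(feats)
        raise KeyError(roi)

    def to_dict(self) -> dict:
        return {
            "entries": [
                {"roi": r, "accuracy": a, "features": list(f)}
                for r, a, f in self.entries
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RoiRanking":
        return cls(
            tuple(
                (int(e["roi"]), float(e["accuracy"]), tuple(e["features"]))
                for e in d["entries"]
            )
        )


def rank_rois(
    feature_table: pd.DataFrame,
    task: TaskSpec,
    n_select_features: int = 20,
    cv_folds: int = 5,
    seed: int = 0,
    newfm_params: Mapping | None = None,
) -> RoiRanking:
    """Rank ROIs by cross-validated accuracy of a per-ROI neuro-fuzzy learner.

    For every ROI a learner is fit on that ROI's 42 features (training
    subjects only); its accuracy is estimated by seeded stratified
    ``cv_folds``-fold cross-validation, and a final fit on all rows yields
    the ROI's ``n_select_features`` most discriminative features.  Ranking is
    by accuracy descending, ties broken by lower ROI index.
    """
    params = dict(newfm_params or {})
    entries = []
    for roi in sorted(feature_table["roi"].unique()):
        X, labels, _ = feature_matrix(feature_table, int(roi))
        y = task.binarize(labels)
        if len(set(y.tolist())) < 2:
            raise ValueError(f"task {task.name}: only one class present")
        accs = []
        for tr, te in _stratified_kfold(y, cv_folds, seed):
            model = NEWFM(n_select=n_select_features, **params).fit(X[tr], y[tr])
            accs.append(float((model.predict(X[te]) == y[te]).mean()))
        final = NEWFM(n_select=n_select_features, **params).fit(X, y)
        entries.append((int(roi), 100.0 * float(np.mean(accs)), tuple(final.selected_)))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return RoiRanking(tuple(entries))


def select_top_rois(ranking: RoiRanking, k: int = 16) -> list[int]:
    """First ``k`` ROIs of the ranking, in rank order."""
    if k > len(ranking.entries):
        raise ValueError(f"asked for {k} ROIs, ranking has {len(ranking.entries)}")
    return ranking.rois()[:k]


def assemble_network_input(
    feature_table: pd.DataFrame,
    ranking: RoiRanking,
    rois: Sequence[int],
    task: TaskSpec,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack the selected ROIs' selected features into one matrix.

    Columns are ordered ROI by ROI (rank order), each ROI contributing its
    selected features in selection order; rows are subjects sorted by id.
    Returns (X, y, subject_ids).
    """
    blocks = []
    y = None
    ids: list[str] = []
    for roi in rois:
        X, labels, ids = feature_matrix(feature_table, int(roi))
        blocks.append(X[:, ranking.selected_features(int(roi))])
        y = task.binarize(labels)
    return np.hstack(blocks), y, ids


# ---------------------------------------------------------------------------
# end-to-end assessment

@dataclasses.dataclass
class EvaluationReport:
    """Everything one assessment run produced."""

    task: str
    split: HoldoutSplit
    selected_rois: list[int]
    layer_accuracies: list[dict]  # per layer: {"layer", "train", "test"} in %
    final_train_accuracy: float
    final_test_accuracy: float
    config: dict

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split"] = {
            "train_ids": list(self.split.train_ids),
            "test_ids": list(self.split.test_ids),
            "seed": self.split.seed,
        }
        return d

    def to_text(self) -> str:
        lines = [
            f"Assessment {self.task}: "
            f"{len(self.split.train_ids)} train / {len(self.split.test_ids)} test subjects",
            f"Selected ROIs (rank order): {self.selected_rois}",
            f"{'Layer':<14}{'Train %':>10}{'Test %':>10}",
        ]
        for e in self.layer_accuracies:
            lines.append(
                f"{e['layer']:<14}{e['train']:>10.1f}{e.get('test', float('nan')):>10.1f}"
            )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def run_assessment(
    subjects: Sequence[SubjectRecord],
    task: TaskSpec | str,
    zlu_counts: Sequence[int] = (16, 4),
    n_train_per_class: int = 23,
    n_top_rois: int = 16,
    n_select_features: int = 20,
    graph_density: float = 0.20,
    n_rewires: int = 20,
    cv_folds: int = 5,
    seed: int = 0,
    newfm_params: Mapping | None = None,
    zlu_params: Mapping | None = None,
    feature_table: pd.DataFrame | None = None,
) -> EvaluationReport:
    """Hold-out split, ROI ranking/selection on the training split only, ZNN
    training, and layerwise scoring of one assessment task.

    ``feature_table`` may carry precomputed features (feature extraction is
    label-free, so sharing it across tasks leaks nothing).
    """
    if isinstance(task, str):
        task = TASKS[task]
    ids = [s.subject_id for s in subjects]
    labels = [s.label for s in subjects]
    split = make_holdout(ids, labels, n_train_per_class, seed)

    if feature_table is None:
        feature_table = extract_cohort_features(
            subjects, graph_density=graph_density, n_rewires=n_rewires, seed=seed
        )
    train_table = feature_table[feature_table["subject_id"].isin(split.train_ids)]
    assert set(train_table["subject_id"]) == set(split.train_ids)

    ranking = rank_rois(
        train_table, task, n_select_features, cv_folds, seed, newfm_params
    )
    top = select_top_rois(ranking, n_top_rois)

    X_train, y_train, _ = assemble_network_input(train_table, ranking, top, task)
    test_table = feature_table[feature_table["subject_id"].isin(split.test_ids)]
    X_test, y_test, _ = assemble_network_input(test_table, ranking, top, task)

    model = ZNN(zlu_counts, dict(newfm_params or {}), dict(zlu_params or {}))
    model.fit(X_train, y_train)
    layers = model.layerwise_accuracies(X_train, y_train, X_test, y_test)

    return EvaluationReport(
        task=task.name,
        split=split,
        selected_rois=top,
        layer_accuracies=layers,
        final_train_accuracy=layers[-1]["train"],
        final_test_accuracy=layers[-1]["test"],
        config={
            "zlu_counts": list(zlu_counts),
            "n_train_per_class": n_train_per_class,
            "n_top_rois": n_top_rois,
            "n_select_features": n_select_features,
            "graph_density": graph_density,
            "n_rewires": n_rewires,
            "cv_folds": cv_folds,
            "seed": seed,
            "newfm_params": dict(newfm_params or {}),
            "zlu_params": dict(zlu_params or {}),
            "feature_names": FEATURE_NAME_MAP,
        },
    )


def roi_overlap(rankings: Sequence[Sequence]) -> set:
    """Intersection of per-task discriminative ROI lists."""
    if len(rankings) != 3:
        raise ValueError("expected one ROI list per assessment (3 lists)")
    sets = []
    for lst in rankings:
        if not isinstance(lst, (list, tuple)) or len(lst) == 0:
            raise ValueError("each ranking must be a non-empty list")
        sets.append(set(lst))
    return sets[0] & sets[1] & sets[2]
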