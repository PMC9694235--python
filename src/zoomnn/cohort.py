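"""Synthetic rs-fMRI cohort generator.

Emulates the data layout of an AAL-atlas resting-state fMRI study: each
subject is a ROIs x timepoints matrix of region-average signals, with a
diagnostic label in {AD, MCI, NC}.  Two class-dependent kinds of structure can
be planted, matching what the downstream feature pipeline is designed to pick
up:

* a slow sinusoid added to designated *informative* ROIs whose amplitude
  scales with the class index — this shifts low-frequency Haar-band energy
  between classes;
* a shared latent factor inside a designated ROI *block* whose loading scales
  with the class index — this shifts inter-ROI correlation (and hence graph
  measures) between classes.

The factor construction keeps the implied correlation matrix positive
semidefinite for any loading in [0, 1).  Everything is driven by a single
integer seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "CLASS_NAMES",
    "CohortSpec",
    "SubjectRecord",
    "generate_cohort",
    "generate_voxel_set",
    "write_cohort",
    "read_cohort",
]

#: Class labels in canonical order; the position in this tuple is the class
#: index that scales the planted effects (AD gets 0x, MCI 1x, NC 2x).
CLASS_NAMES: tuple[str, ...] = ("AD", "MCI", "NC")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Generating parameters for one synthetic cohort.

    Defaults reproduce the reference study shape: 34 AD / 89 MCI / 45 NC
    subjects, 90 ROIs, 140 timepoints.

    Parameters
    ----------
    n_per_class
        Subjects per class label.
    n_rois, n_timepoints
        Matrix dimensions per subject.
    informative_rois
        ROI indices receiving the class-dependent sinusoid.
    spectral_effect
        Amplitude step (signal units) of the planted sinusoid per unit of
        class index.
    connectivity_effect
        Within-block correlation step per unit of class index; the top class
        reaches ``(n_classes - 1) * connectivity_effect``, which must stay
        below 1 for the implied correlation matrix to be valid.
    connectivity_block
        ROI indices sharing the latent factor; defaults to the informative
        ROIs.
    noise_sd
        Scale of the per-ROI background AR(1) process.
    ar_coef
        AR(1) coefficient of background and factor processes.
    sin_period
        Period (timepoints) of the planted sinusoid; 32 lands the effect in
        the level-4 wavelet bands of a 128-point analysis.
    seed
        Root seed; identical spec + seed gives bit-identical cohorts.
    """

    n_per_class: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"AD": 34, "MCI": 89, "NC": 45}
    )
    n_rois: int = 90
    n_timepoints: int = 140
    informative_rois: frozenset[int] | None = None
    spectral_effect: float = 1.0
    connectivity_effect: float = 0.15
    connectivity_block: frozenset[int] | None = None
    noise_sd: float = 1.0
    ar_coef: float = 0.3
    sin_period: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_class:
            raise ValueError("n_per_class must name at least one class")
        for name, count in self.n_per_class.items():
            if name not in CLASS_NAMES:
                raise ValueError(f"unknown class label {name!r}")
            if count <= 0:
                raise ValueError(f"count for class {name!r} must be positive")
        if self.n_rois <= 0 or self.n_timepoints <= 0:
            raise ValueError("n_rois and n_timepoints must be positive")
        if self.informative_rois is None:
            # default: the first eight ROIs (or all of a smaller atlas)
            object.__setattr__(
                self, "informative_rois", frozenset(range(min(8, self.n_rois)))
            )
        else:
            object.__setattr__(self, "informative_rois", frozenset(self.informative_rois))
        bad = [r for r in self.informative_rois if not 0 <= r < self.n_rois]
        if bad:
            raise ValueError(f"informative_rois out of range: {sorted(bad)}")
        if self.connectivity_block is not None:
            bad = [r for r in self.connectivity_block if not 0 <= r < self.n_rois]
            if bad:
                raise ValueError(f"connectivity_block out of range: {sorted(bad)}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.connectivity_effect < 1:
            raise ValueError("connectivity_effect must lie in [0, 1)")
        top = (len(CLASS_NAMES) - 1) * self.connectivity_effect
        if top >= 1.0:
            block = sorted(self.block_rois())
            raise ValueError(
                "connectivity_effect implies within-block correlation "
                f"{top:.3f} >= 1 for block {block}; the implied correlation "
                "matrix would not be positive semidefinite"
            )
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")

    def block_rois(self) -> frozenset[int]:
        """ROI block sharing the latent connectivity factor."""
        if self.connectivity_block is None:
            return self.informative_rois
        return self.connectivity_block

    def total_subjects(self) -> int:
        return sum(self.n_per_class.values())

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_per_class"] = dict(self.n_per_class)
        d["informative_rois"] = sorted(self.informative_rois)
        d["connectivity_block"] = (
            None if self.connectivity_block is None else sorted(self.connectivity_block)
        )
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        if d.get("informative_rois") is not None:
            d["informative_rois"] = frozenset(d["informative_rois"])
        if d.get("connectivity_block") is not None:
            d["connectivity_block"] = frozenset(d["connectivity_block"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class SubjectRecord:
    """One subject: identifier, class label and the ROIs x timepoints matrix."""

    subject_id: str
    label: str
    roi_series: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.roi_series, dtype=float)
        if arr.ndim != 2:
            raise ValueError("roi_series must be 2-D (ROIs x timepoints)")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"roi_series of {self.subject_id} has non-finite values")
        object.__setattr__(self, "roi_series", arr)


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Standardized (unit-variance) stationary AR(1) sample of length ``n``."""
    innov = np.empty(n)
    innov[0] = rng.standard_normal()  # stationary start, variance 1
    innov[1:] = rng.standard_normal(n - 1) * np.sqrt(1.0 - phi * phi)
    return lfilter([1.0], [1.0, -phi], innov)


def _subject_matrix(spec: CohortSpec, class_index: int, rng: np.random.Generator) -> np.ndarray:
    n_r, n_t = spec.n_rois, spec.n_timepoints
    rho = class_index * spec.connectivity_effect
    lam = np.sqrt(rho)
    block = spec.block_rois()

    factor = _ar1(rng, n_t, spec.ar_coef)
    series = np.empty((n_r, n_t))
    for r in range(n_r):
        eps = _ar1(rng, n_t, spec.ar_coef)
        if r in block and lam > 0:
            series[r] = np.sqrt(1.0 - rho) * eps + lam * factor
        else:
            series[r] = eps
    series *= spec.noise_sd

    amp = class_index * spec.spectral_effect
    if amp != 0 and spec.informative_rois:
        t = np.arange(n_t)
        for r in sorted(spec.informative_rois):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            series[r] += amp * np.sin(2.0 * np.pi * t / spec.sin_period + phase)
    return series


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate all subjects of a cohort.

    Subjects are ordered by class (AD, MCI, NC) and index within class.
    Identical ``spec`` (including seed) yields bit-identical output.
    """
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(spec.total_subjects())
    subjects: list[SubjectRecord] = []
    i = 0
    for ci, name in enumerate(CLASS_NAMES):
        for k in range(spec.n_per_class.get(name, 0)):
            rng = np.random.default_rng(streams[i])
            i += 1
            mat = _subject_matrix(spec, ci, rng)
            subjects.append(SubjectRecord(f"sub-{name}-{k:03d}", name, mat))
    return subjects


def generate_voxel_set(
    roi_signal: np.ndarray, n_voxels: int, voxel_noise_sd: float, seed: int
) -> np.ndarray:
    """Simulate the voxel population underlying one ROI signal.

    Each voxel is the ROI signal plus independent Gaussian noise, so the mean
    over voxels converges to the ROI signal as ``n_voxels`` grows.  Returns an
    ``n_voxels x n_timepoints`` array.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    sig = np.asarray(roi_signal, dtype=float)
    if sig.ndim != 1:
        raise ValueError("roi_signal must be 1-D")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_voxels, sig.size)) * voxel_noise_sd
    return sig[None, :] + noise


# ---------------------------------------------------------------------------
# On-disk dialect: one TSV per subject (rows = ROIs, columns = timepoints,
# first column the ROI name) plus a manifest and the generating spec as JSON.

def _roi_names(n_rois: int) -> list[str]:
    return [f"roi_{i:03d}" for i in range(n_rois)]


def write_cohort(subjects: Sequence[SubjectRecord], out_dir: str | Path,
                 spec: CohortSpec | None = None) -> Path:
    """Write subject tables + manifest (+ spec.json); returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in subjects:
        n_r, n_t = sub.roi_series.shape
        df = pd.DataFrame(
            sub.roi_series,
            index=pd.Index(_roi_names(n_r), name="roi"),
            columns=[str(t) for t in range(n_t)],
        )
        fname = f"{sub.subject_id}.tsv"
        df.to_csv(out / fname, sep="\t", float_format="%.17g")
        rows.append({"subject_id": sub.subject_id, "label": sub.label, "path": fname})
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if spec is not None:
        (out / "spec.json").write_text(json.dumps(spec.to_dict(), indent=2) + "\n")
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    """Read a cohort back from its manifest (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    man = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "label", "path"}
    if not required.issubset(man.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    subjects = []
    for row in man.itertuples(index=False):
        df = pd.read_csv(base / row.path, sep="\t", index_col=0,
                         float_precision="round_trip")
        subjects.append(SubjectRecord(str(row.subject_id), str(row.label), df.to_numpy()))
    return subjects
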