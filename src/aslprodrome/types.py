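"""Core in-memory containers for the ASL pipeline.

The pipeline passes data between stages as small dataclasses wrapping numpy
arrays plus the metadata needed to interpret them (affine, volume labels,
repetition time).  On disk everything is NIfTI-1 plus a JSON sidecar, so any
stage can be re-run from serialized artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

M0 = "m0"
LABEL = "label"
CONTROL = "control"


def default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Diagonal RAS affine with the origin at the corner voxel."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge length in mm from an affine."""
    return np.sqrt((affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class AslSeries:
    """A 4D pulsed-ASL acquisition: one M0 calibration volume followed by
    strictly alternating label/control volumes.

    ``data`` is (x, y, z, t) in arbitrary scanner units.  ``volume_labels``
    tags each frame as ``m0``/``label``/``control``; the first frame must be
    the M0 image and the remaining tags must alternate.
    """

    data: np.ndarray
    affine: np.ndarray
    volume_labels: list[str]
    tr_ms: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("AslSeries.data must be 4D (x, y, z, t)")
        if len(self.volume_labels) != self.data.shape[3]:
            raise ValueError("volume_labels length must match number of volumes")
        if self.volume_labels[0] != M0:
            raise ValueError("first volume must be tagged 'm0'")
        tags = self.volume_labels[1:]
        for i, tag in enumerate(tags):
            if tag not in (LABEL, CONTROL):
                raise ValueError(f"invalid volume tag {tag!r}")
            if i > 0 and tag == tags[i - 1]:
                raise ValueError("label/control tags must strictly alternate")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def m0(self) -> np.ndarray:
        return self.data[..., 0]

    @property
    def voxel_size(self) -> np.ndarray:
        return voxel_sizes(self.affine)

    @property
    def pair_indices(self) -> list[tuple[int, int]]:
        """(label_volume, control_volume) index pairs, in acquisition order."""
        pairs = []
        for k in range(1, self.n_volumes - 1, 2):
            a, b = k, k + 1
            if self.volume_labels[a] == LABEL:
                pairs.append((a, b))
            else:
                pairs.append((b, a))
        return pairs

    def copy_with(self, data: np.ndarray) -> "AslSeries":
        return AslSeries(
            data=np.asarray(data, dtype=np.float64),
            affine=self.affine.copy(),
            volume_labels=list(self.volume_labels),
            tr_ms=self.tr_ms,
        )


@dataclass
class TissueMaps:
    """Co-registered GM/WM/CSF probability volumes on the acquisition grid."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.gm.shape, self.wm.shape, self.csf.shape}
        if len(shapes) != 1:
            raise ValueError("tissue maps must share one grid")
        for name in ("gm", "wm", "csf"):
            arr = getattr(self, name)
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise ValueError(f"{name} probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gm.shape

    @property
    def total(self) -> np.ndarray:
        return self.gm + self.wm + self.csf


@dataclass
class CbfSeries:
    """Stack of per-pair quantified CBF maps (ml/100 g/min).

    ``kept`` tracks which maps survive quality control; quantification
    initializes it to all-true.  ``m0_valid`` marks voxels whose M0 signal was
    high enough for quantification (others are zeroed).
    """

    maps: np.ndarray
    pair_index: list[tuple[int, int]]
    kept: np.ndarray
    affine: np.ndarray
    m0_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        self.kept = np.asarray(self.kept, dtype=bool)
        if self.maps.ndim != 4:
            raise ValueError("CbfSeries.maps must be 4D (x, y, z, pair)")
        if self.maps.shape[3] != len(self.pair_index) or self.maps.shape[3] != self.kept.size:
            raise ValueError("pair_index/kept must match number of maps")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[3]


@dataclass
class NuisanceSet:
    """Temporal nuisance regressors, one value per non-M0 volume."""

    motion: np.ndarray  # (T, 6): 3 translations mm, 3 rotations deg
    global_signal: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        t = len(self.global_signal)
        if self.motion.shape != (t, 6) or len(self.wm) != t or len(self.csf) != t:
            raise ValueError("nuisance timecourses must share one length")

    @property
    def n_timepoints(self) -> int:
        return len(self.global_signal)

    def as_matrix(self) -> np.ndarray:
        """Stack the 9 nuisance regressors as columns of a (T, 9) matrix."""
        return np.column_stack(
            [self.motion, self.global_signal, self.wm, self.csf]
        )


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def save_asl_series(path: str | Path, series: AslSeries) -> None:
    """Write the 4D series as NIfTI-1 with a JSON sidecar holding the volume
    tags and TR (information NIfTI cannot carry)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(series.data, series.affine), str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    meta = {"volume_labels": series.volume_labels, "tr_ms": series.tr_ms}
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=2))


def load_asl_series(path: str | Path) -> AslSeries:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = path.with_suffix("").with_suffix("")
    meta = json.loads(Path(str(sidecar) + ".json").read_text())
    return AslSeries(
        data=np.asarray(img.get_fdata(), dtype=np.float64),
        affine=img.affine,
        volume_labels=list(meta["volume_labels"]),
        tr_ms=float(meta["tr_ms"]),
    )


def save_tissue_maps(directory: str | Path, tissue: TissueMaps, prefix: str = "tissue") -> None:
    directory = Path(directory)
    for name in ("gm", "wm", "csf"):
        save_volume(directory / f"{prefix}_{name}.nii.gz", getattr(tissue, name), tissue.affine)


def load_tissue_maps(directory: str | Path, prefix: str = "tissue") -> TissueMaps:
    directory = Path(directory)
    arrays = {}
    affine = None
    for name in ("gm", "wm", "csf"):
        arrays[name], affine = load_volume(directory / f"{prefix}_{name}.nii.gz")
    return TissueMaps(gm=arrays["gm"], wm=arrays["wm"], csf=arrays["csf"], affine=affine)
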