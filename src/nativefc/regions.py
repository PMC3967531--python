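"""Regional signal extraction from label volumes in subject native space.

The central premise of native-space analysis is that regional masks are
defined on each subject's own anatomy, so voxel membership is unambiguous
and no cross-subject warping is needed.  This module holds the image
containers (4D BOLD series, integer label volumes, the time x region
signal matrix), nearest-neighbour label resampling under a single composed
rigid transform, unweighted regional averaging, and the overlay-map
machinery used to quantify how well masks from many subjects align on a
common grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Canonical default-mode-network region abbreviations, in fixed order:
#: hippocampus, entorhinal cortex, inferior parietal lobule, isthmus of the
#: cingulate, medial orbitofrontal cortex, parahippocampal gyrus, posterior
#: cingulate, precuneus, superior-frontal gyrus, supramarginal gyrus.
DMN_REGIONS: tuple[str, ...] = (
    "Hi", "En", "IP", "IC", "MOF", "PHi", "PoC", "PCu", "SF", "SM",
)

HEMISPHERES: tuple[str, str] = ("L", "R")

_AFFINE_ATOL = 1e-6


def _check_affine(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {a.shape}")
    if abs(np.linalg.det(a[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    return a


def same_geometry(affine_a: np.ndarray, shape_a, affine_b: np.ndarray, shape_b) -> bool:
    return tuple(shape_a) == tuple(shape_b) and np.allclose(
        affine_a, affine_b, atol=_AFFINE_ATOL
    )


@dataclass
class BoldSeries4D:
    """A 4D BOLD run: intensities indexed (x, y, z, t) plus grid geometry."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD series needs at least 2 time points")
        self.affine = _check_affine(self.affine)
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path, tr_seconds: float | None = None) -> "BoldSeries4D":
        img = nib.load(str(path))
        tr = tr_seconds if tr_seconds is not None else float(img.header.get_zooms()[3])
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, tr)


@dataclass
class LabelVolume:
    """Integer-coded region map with a label table.

    The table maps each nonzero label id to ``(name, hemisphere, tissue)``
    where hemisphere is ``L``, ``R`` or ``none`` and tissue is one of
    ``gray``, ``white``, ``csf``.  Label 0 is reserved for background.
    """

    data: np.ndarray
    affine: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.int32)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        self.affine = _check_affine(self.affine)
        required = {"id", "name", "hemisphere", "tissue"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"label table must have columns {sorted(required)}")
        present = set(np.unique(self.data)) - {0}
        known = set(self.table["id"].astype(int))
        missing = present - known
        if missing:
            raise ValueError(f"grid labels missing from table: {sorted(missing)}")

    def ids_for(self, tissue: str | None = None, hemisphere: str | None = None) -> list[int]:
        t = self.table
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        if hemisphere is not None:
            t = t[t["hemisphere"] == hemisphere]
        return [int(i) for i in t["id"]]

    def mask(self, label_id: int) -> np.ndarray:
        return self.data == label_id

    def brain_mask(self) -> np.ndarray:
        return self.data > 0

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int32), self.affine), str(path))

    def table_to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_nifti(cls, path, table_path) -> "LabelVolume":
        img = nib.load(str(path))
        table = pd.read_csv(table_path, sep="\t")
        return cls(np.asarray(img.dataobj).astype(np.int32), img.affine, table)


@dataclass
class RegionSignalMatrix:
    """Time x region averaged BOLD signals, the pipeline's central object.

    Columns are a pandas MultiIndex of ``(region name, hemisphere)``.
    """

    data: pd.DataFrame
    tr_seconds: float

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise ValueError("columns must be a (name, hemisphere) MultiIndex")
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("regional signals contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def hemispheres(self) -> list[str]:
        return sorted(set(self.data.columns.get_level_values(1)))

    def column(self, name: str, hemisphere: str) -> np.ndarray:
        return self.data[(name, hemisphere)].to_numpy()

    def with_values(self, values: np.ndarray) -> "RegionSignalMatrix":
        if values.shape[1] != self.data.shape[1]:
            raise ValueError("column count changed")
        return RegionSignalMatrix(
            pd.DataFrame(values, columns=self.data.columns), self.tr_seconds
        )


def canonical_column_order(columns) -> list:
    """Sort (name, hemisphere) pairs by the canonical DMN list, L before R.

    Names outside the canonical list sort after it, alphabetically.
    """
    canon = {name: i for i, name in enumerate(DMN_REGIONS)}

    def key(col):
        name, hemi = col
        return (canon.get(name, len(canon)), name, hemi)

    return sorted(columns, key=key)


def resample_labels(
    labels: LabelVolume,
    rigid_transform: np.ndarray,
    target_affine: np.ndarray,
    target_shape: tuple[int, int, int],
) -> LabelVolume:
    """Nearest-neighbour resampling of a label volume under one composed transform.

    ``rigid_transform`` is a 4x4 world -> world map applied to the image
    content.  All stages of localization are composed into this single
    matrix so that only one interpolation touches the labels; resampling
    twice with the factors would erode boundary voxels twice.
    """
    rigid_transform = _check_affine(rigid_transform)
    target_affine = _check_affine(target_affine)
    # target voxel -> world -> (undo content motion) -> source voxel
    full = np.linalg.inv(labels.affine) @ np.linalg.inv(rigid_transform) @ target_affine
    idx = np.indices(target_shape, dtype=float).reshape(3, -1)
    src = full[:3, :3] @ idx + full[:3, 3:4]
    out = ndimage.map_coordinates(
        labels.data, src, order=0, mode="constant", cval=0, prefilter=False
    ).reshape(target_shape)
    return LabelVolume(out.astype(labels.data.dtype), target_affine, labels.table)


def extract_regional_means(
    bold: BoldSeries4D,
    labels: LabelVolume,
    region_ids: list[int] | None = None,
) -> RegionSignalMatrix:
    """Average all voxels inside each region at every time point.

    Voxels are unweighted; empty regions are excluded with a logged
    warning.  Columns follow the canonical DMN order, left hemisphere
    before right, with non-canonical names after.
    """
    if not same_geometry(bold.affine, bold.shape3d, labels.affine, labels.data.shape):
        raise ValueError("BOLD and label grids have different geometry")
    if region_ids is None:
        region_ids = labels.ids_for(tissue="gray")
    rows = labels.table.set_index("id")
    cols: dict[tuple[str, str], np.ndarray] = {}
    for rid in region_ids:
        mask = labels.mask(int(rid))
        name = str(rows.loc[int(rid), "name"])
        hemi = str(rows.loc[int(rid), "hemisphere"])
        if not mask.any():
            logger.warning("region %s (%s, id=%d) has no voxels; excluded", name, hemi, rid)
            continue
        cols[(name, hemi)] = bold.data[mask].mean(axis=0)
    if not cols:
        raise ValueError("no non-empty regions to extract")
    order = canonical_column_order(cols)
    frame = pd.DataFrame(
        {c: cols[c] for c in order},
        columns=pd.MultiIndex.from_tuples(order, names=["region", "hemisphere"]),
    )
    return RegionSignalMatrix(frame, bold.tr_seconds)


def overlay_map(masks: list[np.ndarray]) -> np.ndarray:
    """Sum binary masks on a common grid into a per-voxel coverage count."""
    if len(masks) == 0:
        raise ValueError("overlay_map needs at least one mask")
    shape = masks[0].shape
    out = np.zeros(shape, dtype=np.int32)
    for i, m in enumerate(masks):
        if m.shape != shape:
            raise ValueError(f"mask {i} shape {m.shape} != {shape}")
        out += (np.asarray(m) > 0).astype(np.int32)
    return out


def containment_fraction(overlay: np.ndarray, reference: np.ndarray) -> float:
    """Fraction of total overlay mass that falls inside the reference region."""
    if overlay.shape != reference.shape:
        raise ValueError("overlay and reference have different shapes")
    total = float(overlay.sum())
    if total == 0:
        raise ValueError("overlay map is empty")
    return float(overlay[np.asarray(reference) > 0].sum()) / total


def gaussian_smooth(
    data: np.ndarray, affine: np.ndarray, fwhm_mm: float, truncate_sd: float = 4.0
) -> np.ndarray:
    """Spatial Gaussian smoothing of a 3D or 4D array, FWHM given in mm."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return data.copy()
    voxdim = np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / voxdim
    if data.ndim == 4:
        sigma = (*sigma_vox, 0.0)
    else:
        sigma = tuple(sigma_vox)
    return ndimage.gaussian_filter(data, sigma=sigma, truncate=truncate_sd)


def random_rigid_transform(jitter_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Small random rigid world->world perturbation.

    Translations are drawn N(0, jitter_mm) per axis; rotations N(0,
    jitter_mm / 50) radians per axis, i.e. the same arc-length scale at a
    50 mm head radius.
    """
    t = rng.normal(0.0, jitter_mm, size=3)
    angles = rng.normal(0.0, jitter_mm / 50.0, size=3)
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    out = np.eye(4)
    out[:3, :3] = rz @ ry @ rx
    out[:3, 3] = t
    return out


def emulate_normalization(bundle, jitter_mm: float, smooth_fwhm_mm: float, seed):
    """Emulate template-space normalization error on a synthetic subject.

    Applies a small random rigid perturbation to the label volume (the
    mask ends up slightly mislocalized, as imperfect spatial normalization
    would leave it) and Gaussian-smooths the BOLD data.  Returns a new
    bundle; with ``jitter_mm == 0`` and ``smooth_fwhm_mm == 0`` it is the
    identity.
    """
    if jitter_mm < 0 or smooth_fwhm_mm < 0:
        raise ValueError("jitter_mm and smooth_fwhm_mm must be >= 0")
    rng = np.random.default_rng(seed)
    labels = bundle.label_volume
    if jitter_mm > 0:
        transform = random_rigid_transform(jitter_mm, rng)
        labels = resample_labels(labels, transform, labels.affine, labels.data.shape)
    bold = bundle.bold
    if smooth_fwhm_mm > 0:
        smoothed = gaussian_smooth(bold.data, bold.affine, smooth_fwhm_mm)
        bold = BoldSeries4D(smoothed, bold.affine, bold.tr_seconds)
    return replace(bundle, label_volume=labels, bold=bold)
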