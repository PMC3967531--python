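"""Motion quality control: framewise displacement, intensity RMSD, scrubbing.

Head motion corrupts resting-state correlations, so contaminated volumes
are identified from two per-volume series — framewise displacement (FD)
computed from the six rigid-body realignment parameters, and the
root-mean-square difference (RMSD) of the percent BOLD signal between
consecutive volumes — and replaced by linear interpolation of clean
neighbours before temporal filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

from .regions import BoldSeries4D, RegionSignalMatrix

logger = logging.getLogger(__name__)

#: Default thresholds: a volume is contaminated when FD > 0.5 mm or
#: RMSD > 0.3 % of the mean signal.
FD_THRESHOLD_MM = 0.5
RMSD_THRESHOLD_PCT = 0.3

#: Head radius used to convert rotations to arc length, per the usual
#: FD convention.
ROTATION_RADIUS_MM = 50.0


@dataclass
class MotionTrace:
    """Per-volume six rigid-body parameters: translations (mm), rotations (rad)."""

    translations: np.ndarray  # (T, 3)
    rotations: np.ndarray  # (T, 3)

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise ValueError("translations and rotations must both be (T, 3)")
        if len(self) < 2:
            raise ValueError("motion trace needs at least 2 volumes")

    def __len__(self) -> int:
        return self.translations.shape[0]

    def to_text(self, path) -> None:
        """Write 6-column whitespace-delimited text, translations first."""
        np.savetxt(path, np.hstack([self.translations, self.rotations]), fmt="%.8f")

    @classmethod
    def from_text(cls, path, order: str = "trans-first", degrees: bool = False) -> "MotionTrace":
        """Read a 6-column motion file.

        ``order`` selects whether the first three columns are translations
        (``trans-first``, the default) or rotations (``rot-first``);
        ``degrees`` converts rotation columns from degrees to radians.
        """
        arr = np.loadtxt(path)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValueError("motion file must have 6 columns")
        if order == "trans-first":
            trans, rot = arr[:, :3], arr[:, 3:]
        elif order == "rot-first":
            rot, trans = arr[:, :3], arr[:, 3:]
        else:
            raise ValueError("order must be 'trans-first' or 'rot-first'")
        if degrees:
            rot = np.deg2rad(rot)
        return cls(trans, rot)


@dataclass
class QcSeries:
    """Per-volume QC: FD (mm), RMSD (%), and the contaminated flags."""

    fd: np.ndarray
    rmsd: np.ndarray
    flags: np.ndarray

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "frame": np.arange(len(self.fd)),
                "fd_mm": self.fd,
                "rmsd_pct": self.rmsd,
                "flagged": self.flags.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)


def framewise_displacement(
    trace: MotionTrace, rotation_radius_mm: float = ROTATION_RADIUS_MM
) -> np.ndarray:
    """FD(i): summed absolute backward differences of the six parameters.

    Rotation differences are converted to arc length on a sphere of
    ``rotation_radius_mm``.  FD(0) = 0 by convention (no predecessor).
    """
    params = np.hstack([trace.translations, trace.rotations * rotation_radius_mm])
    if not np.all(np.isfinite(params)):
        bad = int(np.argwhere(~np.isfinite(params).all(axis=1))[0, 0])
        raise ValueError(f"non-finite motion parameter at volume {bad}")
    fd = np.zeros(len(trace))
    fd[1:] = np.abs(np.diff(params, axis=0)).sum(axis=1)
    return fd


def rmsd_percent(bold: BoldSeries4D, brain_mask: np.ndarray) -> np.ndarray:
    """RMS of the voxelwise percent-signal change between consecutive volumes.

    Each voxel's difference is expressed as a percentage of that voxel's
    temporal mean; voxels with zero temporal mean inside the mask are
    excluded (with a logged count).  Computed on motion-corrected,
    unfiltered data; RMSD(0) = 0.
    """
    mask = np.asarray(brain_mask) > 0
    if mask.shape != bold.shape3d:
        raise ValueError("mask geometry does not match BOLD")
    if not mask.any():
        raise ValueError("brain mask is empty")
    series = bold.data[mask]  # (V, T)
    mu = series.mean(axis=1)
    ok = mu != 0
    n_zero = int((~ok).sum())
    if n_zero:
        logger.warning("excluding %d mask voxels with zero temporal mean", n_zero)
        series = series[ok]
        mu = mu[ok]
        if series.shape[0] == 0:
            raise ValueError("all mask voxels have zero temporal mean")
    pct = np.diff(series, axis=1) / mu[:, None] * 100.0
    rmsd = np.zeros(bold.n_timepoints)
    rmsd[1:] = np.sqrt((pct**2).mean(axis=0))
    return rmsd


def flag_contaminated(
    fd: np.ndarray,
    rmsd: np.ndarray,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    rmsd_threshold_pct: float = RMSD_THRESHOLD_PCT,
) -> np.ndarray:
    """Flag volumes with FD or RMSD strictly above threshold."""
    fd = np.asarray(fd, dtype=float)
    rmsd = np.asarray(rmsd, dtype=float)
    if fd.shape != rmsd.shape:
        raise ValueError("fd and rmsd lengths differ")
    return (fd > fd_threshold_mm) | (rmsd > rmsd_threshold_pct)


def _interpolate_flagged(values: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Replace flagged time points (first axis) by linear interpolation.

    Runs of flagged points are interpolated linearly between the nearest
    clean points on either side; flagged runs touching the series edges
    take the nearest clean value (constant extrapolation).
    """
    flags = np.asarray(flags, dtype=bool)
    t = np.arange(values.shape[0])
    if flags.shape[0] != values.shape[0]:
        raise ValueError("flags length does not match series length")
    if flags.all():
        raise ValueError("all volumes are flagged; nothing to interpolate from")
    if not flags.any():
        return values.copy()
    good = ~flags
    if good.sum() == 1:
        out = values.copy()
        out[flags] = values[good][0]
        return out
    f = interp1d(
        t[good],
        values[good],
        axis=0,
        bounds_error=False,
        fill_value=(values[good][0], values[good][-1]),
        assume_sorted=True,
    )
    out = values.copy()
    out[flags] = f(t[flags])
    return out


def replace_volumes(series, flags):
    """Replace flagged volumes by interpolating their clean neighbours.

    Accepts a :class:`BoldSeries4D` (time is the last axis), a
    :class:`RegionSignalMatrix`, or a plain array with time on the first
    axis, and returns the same type.  Applied before band-pass filtering.
    """
    if isinstance(series, BoldSeries4D):
        moved = np.moveaxis(series.data, 3, 0)
        out = np.moveaxis(_interpolate_flagged(moved, flags), 0, 3)
        return BoldSeries4D(out, series.affine, series.tr_seconds)
    if isinstance(series, RegionSignalMatrix):
        return series.with_values(_interpolate_flagged(series.values, flags))
    return _interpolate_flagged(np.asarray(series, dtype=float), flags)


def qc_series(
    trace: MotionTrace,
    bold: BoldSeries4D,
    brain_mask: np.ndarray,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    rmsd_threshold_pct: float = RMSD_THRESHOLD_PCT,
    rotation_radius_mm: float = ROTATION_RADIUS_MM,
) -> QcSeries:
    """Compute FD, RMSD and contamination flags for one run."""
    fd = framewise_displacement(trace, rotation_radius_mm)
    rmsd = rmsd_percent(bold, brain_mask)
    flags = flag_contaminated(fd, rmsd, fd_threshold_mm, rmsd_threshold_pct)
    return QcSeries(fd=fd, rmsd=rmsd, flags=flags)
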