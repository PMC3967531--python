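"""Temporal processing: band-pass filtering, filter-lag discard, nuisance OLS.

Resting-state connectivity lives in the 0.01-0.08 Hz band: below it sits
scanner drift and 1/f noise, above it respiratory and cardiac
fluctuations (aliased by the 2 s sampling).  Filtering is zero-phase so
that no inter-regional phase shifts are introduced — phase shifts would
directly corrupt lag-zero Pearson correlations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sps

from .regions import BoldSeries4D, RegionSignalMatrix

logger = logging.getLogger(__name__)

DEFAULT_LOW_HZ = 0.01
DEFAULT_HIGH_HZ = 0.08
#: Volumes discarded after filtering to drop the digital filter's settling
#: transient (on the order of the filter order).
DEFAULT_N_DISCARD = 5

#: Ordered nuisance regressors used for residualization.
NUISANCE_COLUMNS = ("fd", "rmsd", "wm_left", "wm_right", "ventricles")


def _design_sos(low_hz: float, high_hz: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high cut-off {high_hz} Hz is at or above Nyquist {nyq} Hz"
        )
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_array(
    values: np.ndarray,
    tr_seconds: float,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = 4,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along ``axis``.

    A 4th-order Butterworth applied forward and backward (zero phase, so
    the effective magnitude response is squared) attenuates by well over
    20 dB one octave outside either cut-off while keeping passband ripple
    below 1 dB.
    """
    sos = _design_sos(low_hz, high_hz, 1.0 / tr_seconds, order)
    return sps.sosfiltfilt(sos, np.asarray(values, dtype=float), axis=axis)


def bandpass(
    series,
    tr_seconds: float | None = None,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = 4,
):
    """Band-pass a :class:`RegionSignalMatrix`, :class:`BoldSeries4D` or array.

    For containers the TR is taken from the object; for a plain array
    (time on the first axis) ``tr_seconds`` is required.
    """
    if isinstance(series, RegionSignalMatrix):
        return series.with_values(
            bandpass_array(series.values, series.tr_seconds, low_hz, high_hz, order)
        )
    if isinstance(series, BoldSeries4D):
        out = bandpass_array(series.data, series.tr_seconds, low_hz, high_hz, order, axis=3)
        return BoldSeries4D(out, series.affine, series.tr_seconds)
    if tr_seconds is None:
        raise ValueError("tr_seconds required for a plain array")
    return bandpass_array(series, tr_seconds, low_hz, high_hz, order)


def discard_lag_volumes(series, n_discard: int = DEFAULT_N_DISCARD):
    """Drop the first ``n_discard`` time points (filter settling lag).

    Works on :class:`RegionSignalMatrix`, :class:`BoldSeries4D`,
    :class:`pandas.DataFrame` or arrays with time on the first axis; any
    aligned series (QC, nuisance) must be passed through the same call so
    alignment is preserved.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if isinstance(series, RegionSignalMatrix):
        if n_discard >= series.n_timepoints:
            raise ValueError("n_discard leaves no time points")
        return RegionSignalMatrix(
            series.data.iloc[n_discard:].reset_index(drop=True), series.tr_seconds
        )
    if isinstance(series, BoldSeries4D):
        if n_discard >= series.n_timepoints:
            raise ValueError("n_discard leaves no time points")
        return BoldSeries4D(series.data[..., n_discard:], series.affine, series.tr_seconds)
    if isinstance(series, pd.DataFrame):
        if n_discard >= len(series):
            raise ValueError("n_discard leaves no time points")
        return series.iloc[n_discard:].reset_index(drop=True)
    arr = np.asarray(series)
    if n_discard >= arr.shape[0]:
        raise ValueError("n_discard leaves no time points")
    return arr[n_discard:]


def build_nuisance(
    fd: np.ndarray,
    rmsd: np.ndarray,
    wm_left: np.ndarray,
    wm_right: np.ndarray,
    ventricles: np.ndarray,
) -> pd.DataFrame:
    """Assemble the standard nuisance set as a named DataFrame."""
    cols = dict(zip(NUISANCE_COLUMNS, (fd, rmsd, wm_left, wm_right, ventricles)))
    lengths = {k: len(v) for k, v in cols.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"nuisance columns have unequal lengths: {lengths}")
    frame = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cols.items()})
    if not np.all(np.isfinite(frame.to_numpy())):
        raise ValueError("nuisance columns contain non-finite values")
    return frame


def _prune_design(nuisance: pd.DataFrame) -> pd.DataFrame:
    """Drop constant or collinear nuisance columns (keeping earlier ones)."""
    kept: list[str] = []
    t = len(nuisance)
    base = np.ones((t, 1))
    for name in nuisance.columns:
        candidate = np.column_stack([base, nuisance[kept + [name]].to_numpy()])
        if np.linalg.matrix_rank(candidate) == candidate.shape[1]:
            kept.append(name)
        else:
            logger.warning("dropping collinear nuisance column %r", name)
    return nuisance[kept]


def residualize(signals, nuisance: pd.DataFrame):
    """Replace each signal by its OLS residual against [intercept | nuisance].

    Rank-deficient designs are repaired by dropping collinear columns
    with a warning; residuals are exactly orthogonal to every retained
    column.  Accepts a :class:`RegionSignalMatrix` or a (T, k) array.
    """
    values = signals.values if isinstance(signals, RegionSignalMatrix) else np.asarray(signals, dtype=float)
    if len(nuisance) != values.shape[0]:
        raise ValueError(
            f"nuisance length {len(nuisance)} != signal length {values.shape[0]}"
        )
    pruned = _prune_design(nuisance)
    design = np.column_stack([np.ones(values.shape[0]), pruned.to_numpy()])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ beta
    if isinstance(signals, RegionSignalMatrix):
        return signals.with_values(resid)
    return resid
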