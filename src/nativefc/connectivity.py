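"""Hemisphere-resolved pairwise Fisher-Z connectivity over the DMN regions.

For ten regions per hemisphere there are 10*9/2 = 45 unordered pairs per
hemisphere, hence 90 hemisphere-resolved values per subject; the
interhemispheric-averaging variant (mean of homologous left/right
signals) yields a further 45.  Correlations are Pearson, on the fully
preprocessed signals, and stored Fisher-Z transformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .regions import DMN_REGIONS, RegionSignalMatrix

_DEGENERATE_TOL = 1e-12


def fisher_z(r) -> np.ndarray | float:
    """Variance-stabilizing Fisher transform z = atanh(r) = 0.5*ln((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| >= 1 has no finite Fisher Z")
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def inverse_fisher_z(z) -> np.ndarray | float:
    """Back-transform z to a correlation: r = tanh(z)."""
    r = np.tanh(np.asarray(z, dtype=float))
    return float(r) if r.ndim == 0 else r


def region_pairs(regions: tuple[str, ...] = DMN_REGIONS) -> list[tuple[str, str]]:
    """All unordered region pairs in canonical (lexicographic-in-list) order."""
    return list(combinations(regions, 2))


def pairwise_connectivity(
    signals: RegionSignalMatrix,
    regions: tuple[str, ...] = DMN_REGIONS,
) -> pd.DataFrame:
    """Pairwise Pearson r and Fisher Z within each hemisphere present.

    Returns a long-format table with columns ``region_a``, ``region_b``,
    ``hemisphere``, ``r``, ``z``; cross-hemisphere pairs are never formed.
    Degenerate correlations (|r| within 1e-12 of 1, i.e. duplicated
    signals upstream) raise rather than storing infinities.
    """
    present = set(signals.data.columns)
    hemis = signals.hemispheres()
    missing = [
        (name, hemi) for hemi in hemis for name in regions if (name, hemi) not in present
    ]
    if missing:
        raise ValueError(f"missing region columns: {missing}")
    records = []
    for hemi in hemis:
        mat = np.column_stack([signals.column(name, hemi) for name in regions])
        corr = np.corrcoef(mat, rowvar=False)
        for (ia, a), (ib, b) in combinations(enumerate(regions), 2):
            r = float(corr[ia, ib])
            if abs(r) >= 1 - _DEGENERATE_TOL:
                raise ValueError(
                    f"degenerate correlation |r|~1 for pair ({a}, {b}) in {hemi}; "
                    "signals are (anti)duplicated upstream"
                )
            records.append(
                {"region_a": a, "region_b": b, "hemisphere": hemi, "r": r, "z": fisher_z(r)}
            )
    return pd.DataFrame.from_records(records)


def average_hemispheres(
    signals: RegionSignalMatrix, regions: tuple[str, ...] = DMN_REGIONS
) -> RegionSignalMatrix:
    """Average homologous left/right signals per region, per time point.

    The result carries hemisphere label ``avg``; pairwise connectivity of
    the averaged matrix yields the 45 averaged-variant values.
    """
    present = set(signals.data.columns)
    missing = [
        (name, hemi) for name in regions for hemi in ("L", "R") if (name, hemi) not in present
    ]
    if missing:
        raise ValueError(f"missing hemisphere partner columns: {missing}")
    cols = {
        (name, "avg"): (signals.column(name, "L") + signals.column(name, "R")) / 2.0
        for name in regions
    }
    frame = pd.DataFrame(
        cols, columns=pd.MultiIndex.from_tuples(cols, names=["region", "hemisphere"])
    )
    return RegionSignalMatrix(frame, signals.tr_seconds)


@dataclass
class ConnectivityRecord:
    """Per-subject Fisher-Z connectivity, hemisphere-resolved (+ optional avg).

    ``table`` is the long-format frame from :func:`pairwise_connectivity`
    (both hemispheres, 90 rows) optionally concatenated with the averaged
    variant (45 more rows with hemisphere ``avg``).
    """

    subject_id: str
    group: str
    table: pd.DataFrame

    def z_values(self, family: str) -> pd.Series:
        """Fisher-Z values for one family (``L``, ``R`` or ``avg``), pair-indexed."""
        sub = self.table[self.table["hemisphere"] == family]
        if sub.empty:
            raise ValueError(f"no values for family {family!r}")
        return pd.Series(
            sub["z"].to_numpy(),
            index=[f"{a}-{b}" for a, b in zip(sub["region_a"], sub["region_b"])],
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def connectivity_record(
    signals: RegionSignalMatrix,
    subject_id: str,
    group: str,
    include_average: bool = True,
    regions: tuple[str, ...] = DMN_REGIONS,
) -> ConnectivityRecord:
    """Build a subject's full connectivity record from preprocessed signals."""
    tables = [pairwise_connectivity(signals, regions)]
    if include_average:
        tables.append(pairwise_connectivity(average_hemispheres(signals, regions), regions))
    return ConnectivityRecord(subject_id, group, pd.concat(tables, ignore_index=True))


def averaged_pair_correlation(
    rho_left: float, rho_right: float, rho_cross: float, rho_homotopic: float
) -> float:
    """Population correlation between two hemisphere-averaged signals.

    For unit-variance signals A, B with within-hemisphere correlations
    ``rho_left``/``rho_right``, cross-hemisphere cross-region correlation
    ``rho_cross`` (corr(A_L, B_R) = corr(A_R, B_L)) and homotopic
    correlation ``rho_homotopic`` (corr(X_L, X_R)):

        corr((A_L+A_R)/2, (B_L+B_R)/2)
            = (rho_left + rho_right + 2*rho_cross) / (2*(1 + rho_homotopic))

    With every pairwise correlation equal to a small rho this is
    2*rho/(1+rho) > rho — averaging inflates weak correlations — while a
    strongly lateralized pair (large rho_right, small rho_left) is pulled
    below its right-hemisphere value: the mixed effect.
    """
    denom = 2.0 * (1.0 + rho_homotopic)
    if denom <= 0:
        raise ValueError("1 + rho_homotopic must be positive")
    return (rho_left + rho_right + 2.0 * rho_cross) / denom
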