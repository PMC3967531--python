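"""End-to-end orchestration: simulate -> scrub -> filter -> extract ->
residualize -> connectivity -> group statistics, as a configured,
logged, reproducible run.

The per-subject preprocessing order is: motion/intensity QC, replacement
of contaminated volumes, zero-phase band-pass, discard of the filter-lag
volumes, regional averaging, then nuisance residualization.  Because
regional averaging is linear and unweighted, residualizing the regional
means is identical to residualizing every voxel first and averaging
after, so the cheap order is used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortSpec,
    SubjectBundle,
    cohort_cognition_table,
    default_dmn_spec,
    simulate_cohort,
    simulate_regional_signals,
)
from .connectivity import (
    ConnectivityRecord,
    connectivity_record,
    inverse_fisher_z,
)
from .motion import QcSeries, qc_series, replace_volumes
from .regions import DMN_REGIONS, BoldSeries4D, RegionSignalMatrix, extract_regional_means
from .stats import COGNITION_FACTORS, cognition_regression, group_compare, hemisphere_interaction
from .temporal import bandpass_array, build_nuisance, discard_lag_volumes, residualize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    fd_threshold_mm: float = 0.5
    rmsd_threshold_pct: float = 0.3
    low_hz: float = 0.01
    high_hz: float = 0.08
    filter_order: int = 4
    n_discard: int = 5
    scrub: bool = True
    nuisance: tuple[str, ...] = ("fd", "rmsd", "wm_left", "wm_right", "ventricles")
    families: tuple[str, ...] = ("both", "avg")
    out_dir: str = "nativefc-run"
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["nuisance"] = list(self.nuisance)
        data["families"] = list(self.families)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("nuisance", "families"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def spec(self) -> CohortSpec:
        overrides = dict(self.cohort)
        overrides.setdefault("seed", self.seed)
        return default_dmn_spec(**overrides)


def preprocess_subject(
    bundle: SubjectBundle, config: RunConfig | None = None
) -> tuple[RegionSignalMatrix, QcSeries]:
    """Run the full per-subject preprocessing chain.

    Returns the preprocessed 20-column regional signal matrix and the QC
    series (FD, RMSD, flags) computed on the raw data.
    """
    config = config or RunConfig()
    labels = bundle.label_volume
    qc = qc_series(
        bundle.motion,
        bundle.bold,
        labels.brain_mask(),
        fd_threshold_mm=config.fd_threshold_mm,
        rmsd_threshold_pct=config.rmsd_threshold_pct,
    )
    # Voxelwise scrubbing and filtering touch only brain voxels: background
    # voxels are identically zero and both operations map zero to zero.
    brain = labels.brain_mask()
    data = bundle.bold.data.copy()
    vox = data[brain]  # (V, T)
    if config.scrub and qc.flags.any():
        vox = replace_volumes(vox.T, qc.flags).T
    vox = bandpass_array(
        vox, bundle.bold.tr_seconds, config.low_hz, config.high_hz,
        config.filter_order, axis=1,
    )
    data[brain] = vox
    bold = BoldSeries4D(data, bundle.bold.affine, bundle.bold.tr_seconds)
    bold = discard_lag_volumes(bold, config.n_discard)
    fd = discard_lag_volumes(qc.fd, config.n_discard)
    rmsd = discard_lag_volumes(qc.rmsd, config.n_discard)

    gray = extract_regional_means(bold, labels, labels.ids_for(tissue="gray"))
    wm = extract_regional_means(bold, labels, labels.ids_for(tissue="white"))
    csf = extract_regional_means(bold, labels, labels.ids_for(tissue="csf"))
    nuisance = build_nuisance(
        fd=fd,
        rmsd=rmsd,
        wm_left=wm.column("white-matter", "L"),
        wm_right=wm.column("white-matter", "R"),
        ventricles=csf.values.mean(axis=1),
    )
    nuisance = nuisance[list(config.nuisance)]
    if len(nuisance.columns):
        gray = residualize(gray, nuisance)
    return gray, qc


def connectivity_for_bundle(
    bundle: SubjectBundle, config: RunConfig | None = None
) -> tuple[ConnectivityRecord, QcSeries]:
    """Preprocess one subject and compute its connectivity record."""
    config = config or RunConfig()
    signals, qc = preprocess_subject(bundle, config)
    include_avg = "avg" in config.families
    return connectivity_record(
        signals, bundle.subject_id, bundle.group, include_average=include_avg
    ), qc


def quick_cohort_records(
    spec: CohortSpec, include_average: bool = True
) -> list[ConnectivityRecord]:
    """Connectivity records straight from the generator's regional signals.

    Skips volume rendering and preprocessing: the simulated signals are
    already clean and band-limited, so this is the fast path for purely
    statistical questions (power, calibration) about the study design.
    """
    records = []
    for i, group in enumerate(spec.subject_groups()):
        signals = simulate_regional_signals(spec, group, spec.subject_seed(i))
        records.append(
            connectivity_record(
                signals, f"sub-{i:02d}", group, include_average=include_average
            )
        )
    return records


def summarize_boxplot(values) -> dict:
    """Five-number boxplot summary plus mean and outliers.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme values within 1.5 IQR of the quartiles and
    outliers are everything beyond.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "mean": float(arr.mean()),
        "outliers": sorted(float(v) for v in arr[(arr < lo_fence) | (arr > hi_fence)]),
    }


def cross_correlogram(
    stats_table: pd.DataFrame, regions: tuple[str, ...] = DMN_REGIONS
) -> dict[str, pd.DataFrame]:
    """10x10 group-mean correlation matrices from a hemisphere-resolved
    stats table: upper triangle right hemisphere, lower triangle left.

    Returns matrices for each group plus a significance annotation matrix
    (empty, ``*`` uncorrected, ``**`` Bonferroni) in the same layout.
    """
    hemis = set(stats_table["hemisphere"])
    if not {"L", "R"}.issubset(hemis):
        raise ValueError("cross-correlogram needs a hemisphere-resolved table")
    idx = {name: i for i, name in enumerate(regions)}
    mats = {
        "young": np.full((10, 10), np.nan),
        "elder": np.full((10, 10), np.nan),
    }
    annot = np.full((10, 10), "", dtype=object)
    for _, row in stats_table.iterrows():
        a, b = row["pair"].split("-")
        i, j = idx[a], idx[b]
        # upper triangle (i < j): right hemisphere; lower: left
        at = (min(i, j), max(i, j)) if row["hemisphere"] == "R" else (max(i, j), min(i, j))
        mats["young"][at] = inverse_fisher_z(row["mean_young"])
        mats["elder"][at] = inverse_fisher_z(row["mean_elder"])
        if row["sig_bonferroni"]:
            annot[at] = "**"
        elif row["sig_uncorrected"]:
            annot[at] = "*"
    out = {
        g: pd.DataFrame(m, index=regions, columns=regions) for g, m in mats.items()
    }
    out["significance"] = pd.DataFrame(annot, index=regions, columns=regions)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full run and write all tables under ``config.out_dir``.

    Writes per-subject QC and connectivity TSVs, per-family group stats
    TSVs, the cross-correlogram CSVs, boxplot summary TSVs, the cognition
    table, the run config (verbatim) and a JSON manifest.  Identical
    config and seed give byte-identical tables.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.spec()

    records: list[ConnectivityRecord] = []
    bundles: list[SubjectBundle] = []
    qc_dir = out / "qc"
    conn_dir = out / "connectivity"
    qc_dir.mkdir(exist_ok=True)
    conn_dir.mkdir(exist_ok=True)
    wanted_hemis: set[str] = set()
    for family in config.families:
        wanted_hemis.update({"both": ["L", "R"], "left": ["L"], "right": ["R"], "avg": ["avg"]}[family])
    flagged_counts = {}
    for bundle in simulate_cohort(spec):
        try:
            record, qc = connectivity_for_bundle(bundle, config)
        except Exception as exc:  # annotate failures with subject context
            raise RuntimeError(
                f"pipeline failed for {bundle.subject_id} ({bundle.group}): {exc}"
            ) from exc
        n_flagged = int(qc.flags.sum())
        flagged_counts[bundle.subject_id] = n_flagged
        logger.info(
            "subject %s (%s): %d/%d volumes flagged and replaced",
            bundle.subject_id, bundle.group, n_flagged, len(qc.flags),
        )
        qc.to_tsv(qc_dir / f"{bundle.subject_id}_qc.tsv")
        written = record.table[record.table["hemisphere"].isin(wanted_hemis)]
        written.to_csv(conn_dir / f"{bundle.subject_id}_connectivity.tsv", sep="\t", index=False)
        records.append(record)
        bundles.append(bundle)

    cohort_cognition_table(bundles).to_csv(out / "cognition.tsv", sep="\t")
    pd.concat(
        [
            r.table[r.table["hemisphere"].isin(wanted_hemis)].assign(
                subject_id=r.subject_id, group=r.group
            )
            for r in records
        ],
        ignore_index=True,
    ).to_csv(out / "connectivity_long.tsv", sep="\t", index=False)

    thresholds = {}
    for family in config.families:
        stats_table = group_compare(records, family=family)
        stats_table.to_csv(out / f"group_stats_{family}.tsv", sep="\t", index=False)
        thresholds[family] = stats_table.attrs["bonferroni_threshold"]
        if family == "both":
            for name, mat in cross_correlogram(stats_table).items():
                mat.to_csv(out / f"cross_correlogram_{name}.csv")
        _boxplot_table(records, family).to_csv(
            out / f"boxplot_summary_{family}.tsv", sep="\t", index=False
        )

    if {"L", "R"} <= wanted_hemis:
        a, b, _ = spec.cognition_model.target_pair
        pair = f"{a}-{b}"  # target pair is stored in canonical region order
        hemisphere_interaction(records, pair).to_csv(
            out / f"hemisphere_interaction_{pair}.tsv", sep="\t"
        )
        cognition = cohort_cognition_table(bundles)
        cog_rows = []
        for hemi in ("L", "R"):
            z = pd.Series(
                {r.subject_id: r.z_values(hemi)[pair] for r in records},
                name="z",
            )
            for group in ("young", "elder"):
                for factor in COGNITION_FACTORS:
                    fit = cognition_regression(z, cognition, factor, group)
                    cog_rows.append(
                        {"pair": pair, "hemisphere": hemi, "group": group,
                         "factor": factor, **fit}
                    )
        pd.DataFrame(cog_rows).to_csv(out / "cognition_stats.tsv", sep="\t", index=False)

    manifest = {
        "package": "nativefc",
        "version": __version__,
        "seed": config.seed,
        "n_subjects": spec.n_subjects(),
        "subjects": [b.subject_id for b in bundles],
        "groups": spec.subject_groups(),
        "families": list(config.families),
        "bonferroni_thresholds": thresholds,
        "flagged_volumes": flagged_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    config.to_yaml(out / "config.yaml")
    return out


def _boxplot_table(records: list[ConnectivityRecord], family: str) -> pd.DataFrame:
    hemis = {"both": ["L", "R"], "left": ["L"], "right": ["R"], "avg": ["avg"]}[family]
    rows = []
    for hemi in hemis:
        frames = {
            g: pd.DataFrame([r.z_values(hemi) for r in records if r.group == g])
            for g in ("young", "elder")
        }
        for pair in frames["young"].columns:
            for g in ("young", "elder"):
                summary = summarize_boxplot(frames[g][pair].to_numpy())
                rows.append(
                    {
                        "pair": pair,
                        "hemisphere": hemi,
                        "group": g,
                        **{k: v for k, v in summary.items() if k != "outliers"},
                        "n_outliers": len(summary["outliers"]),
                    }
                )
    return pd.DataFrame(rows)
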