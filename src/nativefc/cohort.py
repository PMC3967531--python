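"""Synthetic resting-state cohort generator.

Builds complete synthetic subjects — label volume, 4D BOLD, motion trace,
cognition scores — whose statistical structure matches a two-group
(young/elder) resting-state study design: 285 volumes at TR 2 s, ten
default-mode regions per hemisphere with a group-specific population
correlation structure, motion spikes, scanner drift, respiratory-band
noise, and cognition scores linearly related to a named connection's
Fisher-Z.

The headline contrast baked into the default specification is the right
supramarginal-superior-frontal (SM-SF) connection: population correlation
0.5 in the young group versus 0.04 in elders, identical everywhere else.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import fisher_z
from .motion import MotionTrace
from .regions import DMN_REGIONS, BoldSeries4D, LabelVolume, RegionSignalMatrix
from .temporal import bandpass_array

logger = logging.getLogger(__name__)

#: Young group: mean age 25.36 (SD 2.74); elder group: 65.11 (SD 2.98).
AGE_MEAN = {"young": 25.36, "elder": 65.11}
AGE_SD = {"young": 2.74, "elder": 2.98}

GROUPS = ("young", "elder")

#: Baseline intensity painted into every labeled voxel, arbitrary scanner units.
BOLD_BASELINE = 1000.0

#: Default grid: 24 x 24 x 18 voxels at 2 mm isotropic.
GRID_SHAPE = (24, 24, 18)
GRID_AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])

_SPIKE_EDGE_MARGIN = 3  # spikes avoid the first/last 3 frames


def volumes_per_run(scan_minutes: float, tr_seconds: float) -> int:
    """Number of volumes acquired in a run: e.g. 9.5 min at TR 2 s -> 285."""
    if scan_minutes <= 0 or tr_seconds <= 0:
        raise ValueError("scan_minutes and tr_seconds must be positive")
    return int(round(scan_minutes * 60.0 / tr_seconds))


def channel_order(region_names: tuple[str, ...] = DMN_REGIONS) -> list[tuple[str, str]]:
    """The 20 (region, hemisphere) channels, region-major, L before R."""
    return [(name, hemi) for name in region_names for hemi in ("L", "R")]


def channel_index(
    name: str, hemi: str, region_names: tuple[str, ...] = DMN_REGIONS
) -> int:
    return 2 * region_names.index(name) + ("L", "R").index(hemi)


def nearest_correlation(matrix: np.ndarray, min_eig: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``min_eig`` and the result rescaled to unit
    diagonal.  Returns ``(repaired, was_repaired)``.
    """
    m = np.asarray(matrix, dtype=float)
    sym = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    needs_clip = vals.min() < min_eig
    repaired = sym
    if needs_clip:
        repaired = (vecs * np.clip(vals, min_eig, None)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    was_repaired = needs_clip or not np.allclose(repaired, m, atol=1e-12)
    return repaired, was_repaired


def background_correlation_matrix(
    within: float = 0.2,
    between: float = 0.1,
    region_names: tuple[str, ...] = DMN_REGIONS,
) -> np.ndarray:
    """20x20 background structure: ``within`` within a hemisphere, ``between``
    across hemispheres, unit diagonal."""
    chans = channel_order(region_names)
    n = len(chans)
    out = np.empty((n, n))
    for i, (_, hi) in enumerate(chans):
        for j, (_, hj) in enumerate(chans):
            out[i, j] = within if hi == hj else between
    np.fill_diagonal(out, 1.0)
    return out


@dataclass
class CognitionModel:
    """Linear model of cognition factors on one connection's Fisher-Z.

    ``params`` maps ``(group, factor)`` to ``(intercept, slope,
    noise_sd)``; the predictor is the subject's realized Fisher-Z for
    ``target_pair`` (region A, region B, hemisphere).
    """

    params: dict[tuple[str, str], tuple[float, float, float]]
    target_pair: tuple[str, str, str] = ("SF", "SM", "R")

    @classmethod
    def default(cls) -> "CognitionModel":
        # Qualitative pattern: in elders, memory and general fluid ability
        # scale with right SM-SF connectivity; in the young, speed of
        # processing does; vocabulary is unrelated in both groups.
        params: dict[tuple[str, str], tuple[float, float, float]] = {}
        for group in GROUPS:
            for factor in ("memory", "speed", "general_fluid", "vocabulary"):
                params[(group, factor)] = (0.0, 0.0, 1.0)
        params[("elder", "memory")] = (0.0, 3.0, 0.5)
        params[("elder", "general_fluid")] = (0.0, 3.0, 0.5)
        params[("young", "speed")] = (0.0, 3.0, 0.5)
        return cls(params=params)


@dataclass
class CohortSpec:
    """Full description of a synthetic two-group resting-state cohort."""

    n_young: int = 25
    n_elder: int = 26
    n_timepoints: int = 285
    tr_seconds: float = 2.0
    region_names: tuple[str, ...] = DMN_REGIONS
    pop_corr_young: np.ndarray = field(default=None)  # type: ignore[assignment]
    pop_corr_elder: np.ndarray = field(default=None)  # type: ignore[assignment]
    band: tuple[float, float] = (0.01, 0.08)
    # Amplitudes are percent of the baseline intensity.  Together they put a
    # clean frame's intensity RMSD near 0.15 %, comfortably below the 0.3 %
    # contamination threshold, while a default spike reaches ~1 %.
    noise_sd: float = 0.05  # per voxel per volume
    drift_amplitude: float = 0.5  # < 0.01 Hz component
    resp_band_amplitude: float = 0.05  # > 0.1 Hz component
    signal_amplitude_pct: float = 0.2  # regional BOLD fluctuation amplitude
    spike_rate: float = 0.03  # probability per eligible volume
    spike_translation_mm: float = 0.8
    spike_intensity_pct: float = 1.0
    cognition_model: CognitionModel = field(default_factory=CognitionModel.default)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 4 or self.n_elder < 4:
            raise ValueError("need at least 4 subjects per group")
        if self.n_timepoints < 64:
            raise ValueError("need at least 64 time points")
        if len(self.region_names) != 10:
            raise ValueError("exactly 10 region names required")
        nyq = 1.0 / (2.0 * self.tr_seconds)
        low, high = self.band
        if not (0 < low < high < nyq):
            raise ValueError(f"band must satisfy 0 < low < high < Nyquist ({nyq} Hz)")
        if self.pop_corr_young is None:
            self.pop_corr_young = self._default_matrix(0.5)
        if self.pop_corr_elder is None:
            self.pop_corr_elder = self._default_matrix(0.04)
        for label in ("pop_corr_young", "pop_corr_elder"):
            mat = np.asarray(getattr(self, label), dtype=float)
            if mat.shape != (20, 20):
                raise ValueError(f"{label} must be 20x20")
            repaired, changed = nearest_correlation(mat)
            if changed:
                logger.warning("%s repaired to nearest positive-definite correlation", label)
            setattr(self, label, repaired)

    def _default_matrix(self, sm_sf_right: float) -> np.ndarray:
        mat = background_correlation_matrix(region_names=self.region_names)
        i = channel_index("SM", "R", self.region_names)
        j = channel_index("SF", "R", self.region_names)
        mat[i, j] = mat[j, i] = sm_sf_right
        return mat

    def pop_corr(self, group: str) -> np.ndarray:
        if group == "young":
            return self.pop_corr_young
        if group == "elder":
            return self.pop_corr_elder
        raise ValueError(f"unknown group {group!r}")

    def n_subjects(self) -> int:
        return self.n_young + self.n_elder

    def subject_groups(self) -> list[str]:
        return ["young"] * self.n_young + ["elder"] * self.n_elder

    def subject_seed(self, index: int) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.seed, index])


def default_dmn_spec(**overrides) -> CohortSpec:
    """The default study design: n=25/26, T=285 at TR 2 s, band 0.01-0.08 Hz,
    right SM-SF population correlation 0.5 (young) vs 0.04 (elder), and a
    0.2 within- / 0.1 between-hemisphere background."""
    return CohortSpec(**overrides)


def simulate_regional_signals(
    spec: CohortSpec, group: str, subject_seed
) -> RegionSignalMatrix:
    """Band-limited Gaussian signals with the group's population correlation.

    Multivariate white noise with the target 20x20 correlation is drawn,
    band-passed to ``spec.band`` (the same zero-phase filter on every
    channel preserves lag-zero correlations), and standardized per column.
    """
    corr = spec.pop_corr(group)
    vals = np.linalg.eigvalsh(corr)
    if vals.min() <= 0:
        raise ValueError(
            f"population matrix not positive definite after repair "
            f"(min eigenvalue {vals.min():.3g})"
        )
    rng = np.random.default_rng(subject_seed)
    chol = np.linalg.cholesky(corr)
    white = rng.standard_normal((spec.n_timepoints, corr.shape[0]))
    raw = white @ chol.T
    low, high = spec.band
    filtered = bandpass_array(raw, spec.tr_seconds, low, high)
    std = filtered.std(axis=0)
    if np.any(std == 0):
        raise ValueError("degenerate (constant) channel after filtering")
    z = (filtered - filtered.mean(axis=0)) / std
    cols = channel_order(spec.region_names)
    frame = pd.DataFrame(
        z, columns=pd.MultiIndex.from_tuples(cols, names=["region", "hemisphere"])
    )
    return RegionSignalMatrix(frame, spec.tr_seconds)


def draw_spike_frames(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli spike placement, avoiding the first/last 3 frames."""
    eligible = np.arange(_SPIKE_EDGE_MARGIN, spec.n_timepoints - _SPIKE_EDGE_MARGIN)
    hits = rng.random(len(eligible)) < spec.spike_rate
    return eligible[hits]


def simulate_motion_trace(
    spec: CohortSpec,
    spike_frames,
    subject_seed,
    drift_mm: float = 0.05,
) -> MotionTrace:
    """Six-parameter motion: smooth low-amplitude drift plus translation jumps.

    Each spike adds a sustained step of ``spec.spike_translation_mm`` in x
    (the head moves and stays), so framewise displacement exceeds the
    scrubbing threshold exactly at the spike frames for default
    magnitudes.  ``drift_mm`` scales the slow baseline wander (rotations
    wander at ``drift_mm / 50`` radians, the matched arc-length scale).
    """
    t = spec.n_timepoints
    spike_frames = np.asarray(spike_frames, dtype=int)
    if np.any(spike_frames < 1) or np.any(spike_frames >= t):
        bad = spike_frames[(spike_frames < 1) | (spike_frames >= t)]
        raise ValueError(
            f"spike frames {bad.tolist()} outside [1, {t}): frame 0 has no predecessor"
        )
    rng = np.random.default_rng(subject_seed)
    time = np.arange(t) * spec.tr_seconds
    params = np.zeros((t, 6))
    for p in range(6):
        scale = drift_mm if p < 3 else drift_mm / 50.0
        for _ in range(2):
            f = rng.uniform(0.002, 0.008)
            phase = rng.uniform(0, 2 * np.pi)
            params[:, p] += scale * np.sin(2 * np.pi * f * time + phase)
    sign = 1.0
    for k in spike_frames:
        params[k:, 0] += sign * spec.spike_translation_mm
        sign = -sign
    return MotionTrace(translations=params[:, :3], rotations=params[:, 3:])


def build_label_volume(spec: CohortSpec) -> LabelVolume:
    """Block-parcellated label grid: 20 gray DMN regions plus white-matter
    and ventricle compartments per hemisphere, each a 3x3x3 block.

    Left hemisphere occupies x < 12, right x >= 12.  Ids: gray regions
    1..20 (region-major, L before R), white matter 21 (L) / 22 (R),
    lateral ventricles 23 (L) / 24 (R).
    """
    data = np.zeros(GRID_SHAPE, dtype=np.int32)
    rows = []
    x_slots = {"L": (1, 5, 9), "R": (13, 17, 21)}
    y_slots = (2, 7, 12, 17)
    z0 = 7
    for hemi_idx, hemi in enumerate(("L", "R")):
        slots = [(x, y) for x in x_slots[hemi] for y in y_slots]
        compartments = [(name, "gray") for name in spec.region_names]
        compartments += [("white-matter", "white"), ("lateral-ventricle", "csf")]
        for slot, (name, tissue) in zip(slots, compartments):
            if tissue == "gray":
                label = 1 + 2 * spec.region_names.index(name) + hemi_idx
            elif tissue == "white":
                label = 21 + hemi_idx
            else:
                label = 23 + hemi_idx
            x0, y0 = slot
            data[x0 : x0 + 3, y0 : y0 + 3, z0 : z0 + 3] = label
            rows.append(
                {"id": label, "name": name, "hemisphere": hemi, "tissue": tissue}
            )
    table = pd.DataFrame(rows).sort_values("id").reset_index(drop=True)
    return LabelVolume(data, GRID_AFFINE.copy(), table)


@dataclass
class SubjectBundle:
    """One complete synthetic subject."""

    subject_id: str
    group: str
    label_volume: LabelVolume
    bold: BoldSeries4D
    motion: MotionTrace
    true_regional_signals: RegionSignalMatrix
    spike_frames: np.ndarray
    cognition: dict

    def __post_init__(self) -> None:
        if self.bold.n_timepoints != len(self.motion):
            raise ValueError("BOLD and motion lengths differ")


def render_subject(spec: CohortSpec, group: str, subject_seed, subject_id: str = "sub-00") -> SubjectBundle:
    """Render a full synthetic subject: paint regional signals into the
    label grid, add noise, drift, respiratory-band fluctuation and spike
    perturbations, and draw a matched motion trace and cognition scores."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    ss = np.random.SeedSequence(subject_seed) if not isinstance(
        subject_seed, np.random.SeedSequence
    ) else subject_seed
    sig_ss, nuis_ss, noise_ss, mot_ss, cog_ss = ss.spawn(5)

    labels = build_label_volume(spec)
    signals = simulate_regional_signals(spec, group, sig_ss)
    t = spec.n_timepoints
    amp = BOLD_BASELINE * spec.signal_amplitude_pct / 100.0

    # painted ground truth for the 20 gray regions
    painted = BOLD_BASELINE + amp * signals.values
    true_signals = signals.with_values(painted)

    # independent band-limited processes for white matter and ventricles
    nuis_rng = np.random.default_rng(nuis_ss)
    low, high = spec.band
    nuis_raw = bandpass_array(
        nuis_rng.standard_normal((t, 4)), spec.tr_seconds, low, high
    )
    nuis = (nuis_raw - nuis_raw.mean(axis=0)) / nuis_raw.std(axis=0)

    bold = np.zeros((*GRID_SHAPE, t))
    chans = channel_order(spec.region_names)
    for idx, (name, hemi) in enumerate(chans):
        label = 1 + 2 * spec.region_names.index(name) + ("L", "R").index(hemi)
        bold[labels.mask(label)] = painted[:, idx]
    for k, label in enumerate((21, 22, 23, 24)):
        bold[labels.mask(label)] = BOLD_BASELINE + amp * nuis[:, k]

    brain = labels.brain_mask()
    noise_rng = np.random.default_rng(noise_ss)
    time = np.arange(t) * spec.tr_seconds
    # shared slow drift (< 0.01 Hz) and respiratory-band (> 0.1 Hz) components
    f_drift = noise_rng.uniform(0.003, 0.008)
    f_resp = noise_rng.uniform(0.15, 0.24)
    global_wave = BOLD_BASELINE / 100.0 * (
        spec.drift_amplitude * np.sin(2 * np.pi * f_drift * time + noise_rng.uniform(0, 2 * np.pi))
        + spec.resp_band_amplitude
        * np.sin(2 * np.pi * f_resp * time + noise_rng.uniform(0, 2 * np.pi))
    )
    bold[brain] += global_wave
    if spec.noise_sd > 0:
        bold[brain] += noise_rng.normal(
            0.0, BOLD_BASELINE / 100.0 * spec.noise_sd, size=(int(brain.sum()), t)
        )

    spike_frames = draw_spike_frames(spec, noise_rng)
    for k in spike_frames:
        bold[..., k][brain] *= 1.0 + spec.spike_intensity_pct / 100.0

    motion = simulate_motion_trace(spec, spike_frames, mot_ss)

    cog_rng = np.random.default_rng(cog_ss)
    a, b, hemi = spec.cognition_model.target_pair
    r = float(
        np.corrcoef(signals.column(a, hemi), signals.column(b, hemi))[0, 1]
    )
    z = fisher_z(r)
    cognition = {"age": float(cog_rng.normal(AGE_MEAN[group], AGE_SD[group])), "z_target": z}
    for factor in ("memory", "speed", "general_fluid", "vocabulary"):
        intercept, slope, sd = spec.cognition_model.params[(group, factor)]
        cognition[factor] = float(intercept + slope * z + cog_rng.normal(0.0, sd))

    return SubjectBundle(
        subject_id=subject_id,
        group=group,
        label_volume=labels,
        bold=BoldSeries4D(bold, GRID_AFFINE.copy(), spec.tr_seconds),
        motion=motion,
        true_regional_signals=true_signals,
        spike_frames=spike_frames,
        cognition=cognition,
    )


def simulate_cohort(spec: CohortSpec):
    """Yield rendered subjects for the whole cohort, deterministically."""
    for i, group in enumerate(spec.subject_groups()):
        yield render_subject(spec, group, spec.subject_seed(i), subject_id=f"sub-{i:02d}")


def cohort_cognition_table(bundles: list[SubjectBundle]) -> pd.DataFrame:
    """Assemble the per-subject cognition table (group, age, four factors)."""
    rows = []
    for b in bundles:
        row = {"subject_id": b.subject_id, "group": b.group}
        row.update(b.cognition)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def write_cohort(spec: CohortSpec, out_dir) -> Path:
    """Render and write a cohort to disk: per-subject NIfTI BOLD and labels,
    motion text, a shared label table TSV, a cognition TSV and a JSON
    manifest.  Returns the cohort directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundles = []
    for bundle in simulate_cohort(spec):
        sub_dir = out / bundle.subject_id
        sub_dir.mkdir(exist_ok=True)
        bundle.bold.to_nifti(sub_dir / "bold.nii.gz")
        bundle.label_volume.to_nifti(sub_dir / "labels.nii.gz")
        bundle.motion.to_text(sub_dir / "motion.txt")
        bundles.append(bundle)
    bundles[0].label_volume.table_to_tsv(out / "labels.tsv")
    cohort_cognition_table(bundles).to_csv(out / "cognition.tsv", sep="\t")
    manifest = {
        "n_subjects": spec.n_subjects(),
        "groups": spec.subject_groups(),
        "subject_ids": [b.subject_id for b in bundles],
        "n_timepoints": spec.n_timepoints,
        "tr_seconds": spec.tr_seconds,
        "seed": spec.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
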