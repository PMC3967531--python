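"""The synthetic cohort generator: signals, motion, rendering, cognition."""

import numpy as np
import pytest
from scipy import signal as sps

import nativefc as nf
from nativefc.cohort import (
    background_correlation_matrix,
    build_label_volume,
    channel_index,
    nearest_correlation,
    volumes_per_run,
)
from nativefc.motion import framewise_displacement, rmsd_percent
from nativefc.regions import extract_regional_means


class TestDefaultSpec:
    def test_study_design_constants(self):
        spec = nf.default_dmn_spec()
        assert spec.n_young == 25
        assert spec.n_elder == 26
        assert spec.n_subjects() == 51
        assert spec.n_timepoints == 285
        assert spec.tr_seconds == 2.0
        assert spec.band == (0.01, 0.08)

    def test_headline_contrast_entries(self):
        spec = nf.default_dmn_spec()
        i, j = channel_index("SM", "R"), channel_index("SF", "R")
        assert spec.pop_corr_young[i, j] == pytest.approx(0.5, abs=1e-6)
        assert spec.pop_corr_elder[i, j] == pytest.approx(0.04, abs=1e-6)

    def test_population_matrices_are_correlations(self):
        spec = nf.default_dmn_spec()
        for mat in (spec.pop_corr_young, spec.pop_corr_elder):
            assert np.allclose(mat, mat.T)
            assert np.allclose(np.diag(mat), 1.0)
            assert np.linalg.eigvalsh(mat).min() > 0

    def test_background_structure(self):
        mat = background_correlation_matrix()
        assert mat[channel_index("Hi", "L"), channel_index("En", "L")] == 0.2
        assert mat[channel_index("Hi", "L"), channel_index("En", "R")] == 0.1

    def test_non_psd_user_matrix_repaired_and_reported(self, caplog):
        bad = background_correlation_matrix()
        bad[0, 1] = bad[1, 0] = 0.999
        bad[0, 2] = bad[2, 0] = 0.999
        bad[1, 2] = bad[2, 1] = -0.999  # infeasible triple
        with caplog.at_level("WARNING"):
            spec = nf.default_dmn_spec(pop_corr_young=bad)
        assert "repaired" in caplog.text
        assert np.linalg.eigvalsh(spec.pop_corr_young).min() > 0

    def test_nearest_correlation_identity_on_valid_input(self):
        good = background_correlation_matrix()
        repaired, changed = nearest_correlation(good)
        assert not changed
        assert np.allclose(repaired, good)

    @pytest.mark.parametrize(
        "kwargs", [{"n_young": 3}, {"n_timepoints": 32}, {"band": (0.1, 0.3)}]
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            nf.default_dmn_spec(**kwargs)


class TestVolumesPerRun:
    def test_nine_and_a_half_minutes_at_tr_two(self):
        assert volumes_per_run(9.5, 2.0) == 285


class TestSimulateRegionalSignals:
    def test_identity_correlation_stays_near_zero(self):
        eye = np.eye(20)
        spec = nf.default_dmn_spec(n_timepoints=4096, pop_corr_young=eye, seed=1)
        sig = nf.simulate_regional_signals(spec, "young", 5)
        corr = np.corrcoef(sig.values, rowvar=False)
        off = corr[np.triu_indices(20, 1)]
        # band-limiting leaves ~T * 2 * (high-low) * TR effective samples, so
        # the sampling SD of each of the 190 correlations is ~1/sqrt(T_eff);
        # bound the maximum at four such SDs
        t_eff = 4096 * 2 * (0.08 - 0.01) * 2.0
        assert np.abs(off).max() < 4.0 / np.sqrt(t_eff)

    def test_target_pair_converges_to_population_value(self):
        """Monte-Carlo oracle: at T=4096 the mean sample correlation of a
        pair planted at 0.5 lands within +/- 0.03 of 0.5."""
        mat = np.eye(20)
        mat[0, 1] = mat[1, 0] = 0.5
        spec = nf.default_dmn_spec(n_timepoints=4096, pop_corr_young=mat, seed=2)
        rs = []
        for rep in range(200):
            sig = nf.simulate_regional_signals(spec, "young", rep)
            rs.append(np.corrcoef(sig.values[:, 0], sig.values[:, 1])[0, 1])
        assert np.mean(rs) == pytest.approx(0.5, abs=0.03)

    def test_deterministic_under_fixed_seed(self, small_spec):
        a = nf.simulate_regional_signals(small_spec, "elder", 9)
        b = nf.simulate_regional_signals(small_spec, "elder", 9)
        assert np.array_equal(a.values, b.values)

    def test_band_limited_power(self):
        """Power outside the filter's stopband edges (half the low cut-off,
        twice the high) is below 1% of the total; the octave-wide
        transition skirts are part of the band-pass design."""
        spec = nf.default_dmn_spec(n_timepoints=2048, seed=3)
        sig = nf.simulate_regional_signals(spec, "young", 7)
        f, pxx = sps.periodogram(sig.values, fs=0.5, axis=0, detrend="constant")
        inband = (f >= 0.005) & (f <= 0.16)
        assert pxx[~inband].sum() / pxx.sum() < 0.01


class TestSimulateMotionTrace:
    def test_no_spikes_zero_drift_is_still(self, small_spec):
        trace = nf.simulate_motion_trace(small_spec, [], 1, drift_mm=0.0)
        assert np.array_equal(framewise_displacement(trace), np.zeros(len(trace)))

    def test_spike_translation_drives_fd(self):
        spec = nf.default_dmn_spec(spike_translation_mm=0.6)
        trace = nf.simulate_motion_trace(spec, [40], 1, drift_mm=0.0)
        fd = framewise_displacement(trace)
        assert fd[40] >= 0.6
        assert (fd > 0.5).sum() == 1  # FD exceeds threshold exactly at the spike

    def test_drift_stays_below_threshold(self, small_spec):
        trace = nf.simulate_motion_trace(small_spec, [], 2)
        assert framewise_displacement(trace).max() < 0.5

    def test_spike_at_frame_zero_rejected(self, small_spec):
        with pytest.raises(ValueError, match="predecessor"):
            nf.simulate_motion_trace(small_spec, [0], 1)


class TestRenderSubject:
    def test_painting_then_averaging_is_identity(self, clean_spec):
        """With all artifact sources off, extracted means equal the truth."""
        bundle = nf.render_subject(clean_spec, "young", 4)
        extracted = extract_regional_means(
            bundle.bold, bundle.label_volume, bundle.label_volume.ids_for(tissue="gray")
        )
        assert np.allclose(extracted.values, bundle.true_regional_signals.values, atol=1e-9)

    def test_intensity_spike_exceeds_rmsd_threshold(self):
        spec = nf.default_dmn_spec(
            n_young=4, n_elder=4, n_timepoints=128,
            spike_rate=0.1, spike_intensity_pct=1.0, seed=17,
        )
        bundle = nf.render_subject(spec, "young", 6)
        assert len(bundle.spike_frames) > 0
        rmsd = rmsd_percent(bundle.bold, bundle.label_volume.brain_mask())
        # a spike frame following another spike has no intensity step, so
        # only spikes with a clean predecessor must exceed the threshold
        spikes = set(bundle.spike_frames.tolist())
        isolated = [k for k in spikes if k - 1 not in spikes]
        assert len(isolated) > 0
        assert (rmsd[isolated] > 0.3).all()

    def test_bit_identical_under_fixed_seed(self, small_spec):
        a = nf.render_subject(small_spec, "elder", 11)
        b = nf.render_subject(small_spec, "elder", 11)
        assert np.array_equal(a.bold.data, b.bold.data)
        assert np.array_equal(a.motion.translations, b.motion.translations)
        assert a.cognition == b.cognition
        assert np.array_equal(a.spike_frames, b.spike_frames)

    def test_spikes_avoid_run_edges(self):
        spec = nf.default_dmn_spec(
            n_young=4, n_elder=4, n_timepoints=64, spike_rate=0.5, seed=23
        )
        bundle = nf.render_subject(spec, "young", 1)
        assert bundle.spike_frames.min() >= 3
        assert bundle.spike_frames.max() < 64 - 3

    def test_group_contrast_has_correct_sign(self, small_spec):
        """Across seeds, young exceed elders on the right SM-SF sample z."""
        diffs = []
        for rep in range(20):
            zs = {}
            for group in ("young", "elder"):
                bundle = nf.render_subject(small_spec, group, [rep, 0])
                s = bundle.true_regional_signals
                zs[group] = np.arctanh(
                    np.corrcoef(s.column("SM", "R"), s.column("SF", "R"))[0, 1]
                )
            diffs.append(zs["young"] - zs["elder"])
        assert np.mean(diffs) > 0

    def test_label_geometry(self, small_spec):
        labels = build_label_volume(small_spec)
        assert labels.data.shape == (24, 24, 18)
        counts = {int(i): int((labels.data == i).sum()) for i in labels.table["id"]}
        assert all(c >= 8 for c in counts.values())  # every compartment >= 8 voxels
        gray = labels.ids_for(tissue="gray")
        assert len(gray) == 20
        assert len(labels.ids_for(tissue="white")) == 2
        assert len(labels.ids_for(tissue="csf")) == 2


class TestCalibration:
    def test_mean_recovered_correlation_near_population_value(self):
        """Mean back-transformed right SM-SF correlation across 25 noiseless
        young subjects lies within +/- 0.06 of the population 0.5."""
        spec = nf.default_dmn_spec(noise_sd=0.0, seed=3)
        rs = []
        for i in range(25):
            s = nf.simulate_regional_signals(spec, "young", spec.subject_seed(i))
            z = np.arctanh(np.corrcoef(s.column("SM", "R"), s.column("SF", "R"))[0, 1])
            rs.append(np.tanh(z))
        assert np.mean(rs) == pytest.approx(0.5, abs=0.06)


class TestCognition:
    def test_generating_slope_recovered(self):
        """Regressing simulated cognition on realized Fisher-Z recovers the
        generating slope within two standard errors."""
        import statsmodels.api as sm

        spec = nf.default_dmn_spec(n_young=4, n_elder=4, n_timepoints=64, seed=29)
        z, y = [], []
        for rep in range(150):
            bundle = nf.render_subject(spec, "elder", [rep, 1])
            z.append(bundle.cognition["z_target"])
            y.append(bundle.cognition["memory"])
        fit = sm.OLS(y, sm.add_constant(np.asarray(z))).fit()
        slope_true = spec.cognition_model.params[("elder", "memory")][1]
        assert abs(fit.params[1] - slope_true) < 2 * fit.bse[1]

    def test_ages_match_group_distributions(self, small_spec):
        bundles = list(nf.simulate_cohort(small_spec))
        young = [b.cognition["age"] for b in bundles if b.group == "young"]
        elder = [b.cognition["age"] for b in bundles if b.group == "elder"]
        assert max(young) < min(elder)  # 25ish vs 65ish, 4 subjects each


class TestCohortIO:
    def test_write_cohort_layout(self, tmp_path):
        import json

        spec = nf.default_dmn_spec(n_young=4, n_elder=4, n_timepoints=64, seed=31)
        out = nf.write_cohort(spec, tmp_path / "cohort")
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["n_subjects"] == 8
        sub = out / manifest["subject_ids"][0]
        assert (sub / "bold.nii.gz").exists()
        assert (sub / "labels.nii.gz").exists()
        assert (sub / "motion.txt").exists()
        assert (out / "cognition.tsv").exists()
        # round trip one subject through the readers
        from nativefc.regions import BoldSeries4D, LabelVolume

        bold = BoldSeries4D.from_nifti(sub / "bold.nii.gz", tr_seconds=2.0)
        labels = LabelVolume.from_nifti(sub / "labels.nii.gz", out / "labels.tsv")
        assert bold.n_timepoints == 64
        assert set(labels.table["tissue"]) == {"gray", "white", "csf"}
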