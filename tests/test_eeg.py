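"""EEG pipeline: preprocessing, epoching, artifact cascade, ERP averaging,
GFP measures and spatial-template projection."""

import numpy as np
import pytest

from nvcouple.eeg import (
    ERPEpochSet,
    GFPSeries,
    SubjectERP,
    average_erp,
    build_templates,
    compute_gfp,
    epoch_trials,
    gfp_peak_measures,
    preprocess_eeg,
    project_templates,
    reject_artifacts,
)
from nvcouple.synthetic import RawEEGRecording

FS_RAW = 2048.0
FS = 512.0


def _raw(volt, t_start=-2.0, fs=FS_RAW):
    labels = tuple(f"E{i}" for i in range(volt.shape[0]))
    return RawEEGRecording(sampling_rate_hz=fs, labels=labels, voltage=volt, t_start_s=t_start)


def _epochs(trials, fs=FS):
    labels = tuple(f"E{i}" for i in range(trials.shape[1]))
    return ERPEpochSet(
        sampling_rate_hz=fs, labels=labels, window_s=(-0.5, 3.5), trials=trials
    )


def _erp(volt, fs=FS):
    labels = tuple(f"E{i}" for i in range(volt.shape[0]))
    return SubjectERP(
        sampling_rate_hz=fs, labels=labels, window_s=(-0.5, 3.5), voltage=volt,
        n_trials_retained=1,
    )


class TestPreprocess:
    def test_decimation_length(self, rng):
        out = preprocess_eeg(_raw(rng.normal(size=(3, 8192))))
        assert out.voltage.shape[-1] == 2048
        assert out.sampling_rate_hz == FS

    def test_dc_removed(self):
        out = preprocess_eeg(_raw(np.full((2, 16384), 100.0)))
        assert np.abs(out.voltage.mean()) < 0.1

    def test_passband_tone_preserved(self):
        t = np.arange(40960) / FS_RAW
        x = np.sin(2 * np.pi * 10.0 * t)[None]
        out = preprocess_eeg(_raw(x))
        td = t[::4]
        z = out.voltage[0] * np.exp(-2j * np.pi * 10.0 * td)
        amp = 2 * np.abs(z[1000:-1000].mean())
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_rate_mismatch_rejected(self):
        with pytest.raises(ValueError):
            preprocess_eeg(_raw(np.zeros((2, 1000)), fs=1000.0))


class TestEpoching:
    def test_five_epochs_per_block(self, schedule_1, rng):
        n = int(62 * FS)
        rec = _raw(rng.normal(size=(3, n)), t_start=-2.0, fs=FS)
        ep = epoch_trials(rec, schedule_1)
        assert ep.n_trials == 5
        assert ep.trials.shape[-1] == 2048  # 4 s x 512 Hz

    def test_constant_input_annihilated_by_baseline(self, schedule_1):
        n = int(62 * FS)
        rec = _raw(np.full((2, n), 7.0), t_start=-2.0, fs=FS)
        ep = epoch_trials(rec, schedule_1)
        assert np.max(np.abs(ep.trials)) < 1e-12

    def test_out_of_bounds_trials_skipped_with_warning(self, schedule_1):
        rec = _raw(np.zeros((2, int(10 * FS))), t_start=-2.0, fs=FS)  # too short
        with pytest.warns(UserWarning, match="skipped"):
            ep = epoch_trials(rec, schedule_1)
        assert ep.n_trials < 5


class TestArtifactRejection:
    def test_absolute_threshold_flags_cell(self, rng):
        x = rng.normal(scale=3.0, size=(4, 31, 2048))
        x[2, 5, 100] = 60.0
        out = reject_artifacts(_epochs(x))
        assert out.channel_reject[2, 5]
        assert out.channel_reject.sum() == 1

    def test_jump_rule_catches_subthreshold_ramp(self):
        x = np.zeros((1, 31, 2048))
        x[0, 3, 500:510] = np.linspace(0, 35, 10)  # peak 35 µV < 50, jump 35 > 30
        out = reject_artifacts(_epochs(x))
        assert out.channel_reject[0, 3]
        assert np.abs(x).max() < 50

    def test_trial_rejected_above_fifteen_percent(self):
        x = np.zeros((2, 31, 2048))
        for e in range(5):  # 5/31 = 16.1 % of electrodes flagged in trial 0
            x[0, e, 10] = 60.0
        out = reject_artifacts(_epochs(x))
        assert list(out.trial_retained) == [False, True]

    def test_session_rule_runs_before_trial_rule(self):
        # electrode 0 bad on all trials -> dropped for the session; remaining
        # flags in trial 0 are 4/30 = 13.3 % <= 15 %, so the trial survives
        x = np.zeros((10, 31, 2048))
        x[:, 0, 5] = 60.0
        for e in range(1, 5):
            x[0, e, 5] = 60.0
        out = reject_artifacts(_epochs(x))
        assert not out.electrode_retained[0]
        assert out.trial_retained[0]

    def test_all_trials_rejected_raises(self):
        x = np.full((2, 4, 100), 80.0)
        with pytest.raises(ValueError, match="all trials rejected"):
            reject_artifacts(_epochs(x))


class TestAveraging:
    def test_identical_trials_average_to_one_trial(self, rng):
        one = rng.normal(size=(3, 256))
        ep = _epochs(np.tile(one, (6, 1, 1)))
        erp = average_erp(ep)
        assert np.allclose(erp.voltage, one)
        assert erp.n_trials_retained == 6

    def test_noise_suppression_scales_with_sqrt_n(self, rng):
        n_trials, sigma = 400, 2.0
        ep = _epochs(rng.normal(scale=sigma, size=(n_trials, 2, 512)))
        erp = average_erp(ep)
        rms = np.sqrt(np.mean(erp.voltage**2))
        assert rms == pytest.approx(sigma / np.sqrt(n_trials), rel=0.2)

    def test_session_rejected_electrodes_become_nan(self, rng):
        ep = _epochs(rng.normal(size=(4, 3, 128)))
        ep.trial_retained = np.array([True, True, False, True])
        ep.electrode_retained = np.array([True, False, True])
        erp = average_erp(ep)
        assert np.isnan(erp.voltage[1]).all()
        assert np.isfinite(erp.voltage[[0, 2]]).all()


class TestGFP:
    def test_uniform_map_zero_gfp(self):
        erp = _erp(np.ones((5, 100)) * 3.3)
        assert np.allclose(compute_gfp(erp).gfp, 0.0)

    def test_reference_translation_invariance(self, rng):
        v = rng.normal(size=(7, 200))
        a = compute_gfp(_erp(v)).gfp
        b = compute_gfp(_erp(v + rng.normal(size=(1, 200)))).gfp
        assert np.allclose(a, b)

    def test_matches_population_sd(self):
        n = 10
        v = np.zeros((n, 1))
        v[0], v[1] = 1.0, -1.0
        expected = np.std(v[:, 0], ddof=0)
        assert compute_gfp(_erp(v)).gfp[0] == pytest.approx(expected)

    def test_needs_two_electrodes(self):
        with pytest.raises(ValueError):
            compute_gfp(_erp(np.ones((1, 10))))


class TestGFPPeakMeasures:
    def test_constant_gfp_gives_constant_matrix(self):
        g = GFPSeries(FS, (-0.5, 3.5), np.full(2048, 2.5))
        m = gfp_peak_measures(g)
        assert m.shape == (4, 4)
        assert np.allclose(m, 2.5)

    def test_window_outside_epoch_raises(self):
        g = GFPSeries(FS, (-0.5, 0.5), np.ones(512))
        with pytest.raises(ValueError):
            gfp_peak_measures(g)

    def test_habituation_ratio_recovered_noiseless(self, montage, schedule_2, noiseless_params):
        from nvcouple.eeg import eeg_subject_pipeline
        from nvcouple.synthetic import simulate_eeg

        rec = simulate_eeg(noiseless_params, schedule_2, montage, seed=0)
        erp = eeg_subject_pipeline(rec, schedule_2)
        m = gfp_peak_measures(compute_gfp(erp))
        ratios = m[:, 1:] / m[:, :-1]
        assert np.abs(ratios.mean() - noiseless_params.habituation_ratio) < 0.05 * 0.8
        assert np.all(np.abs(ratios - 0.8) < 0.25)  # no single wild step


class TestTemplates:
    def _cohort(self, maps, n_samples=2048):
        """Subjects whose ERP is map x a fixed temporal profile."""
        t = -0.5 + np.arange(n_samples) / FS
        profile = np.exp(-((t - 0.244) ** 2) / (2 * 0.04**2))
        return [_erp(np.outer(m, profile)) for m in maps]

    def test_identical_subjects_any_fold(self, rng):
        m = rng.normal(size=12)
        erps = self._cohort([m] * 4)
        full = build_templates(erps, ["a", "b", "c", "d"])
        loo = build_templates(erps, ["a", "b", "c", "d"], leave_out="b")
        for f, l in zip(full, loo):
            assert np.allclose(f.weights, l.weights)
            centred = m - m.mean()
            expected = centred / np.linalg.norm(centred)
            sign = np.sign(f.weights @ expected)
            assert np.allclose(f.weights, sign * expected, atol=1e-9)

    def test_unit_norm_every_fold(self, rng):
        erps = self._cohort(rng.normal(size=(5, 12)))
        ids = [f"s{i}" for i in range(5)]
        for leave in [None] + ids:
            for tpl in build_templates(erps, ids, leave_out=leave):
                assert np.linalg.norm(tpl.weights) == pytest.approx(1.0, abs=1e-12)
                assert tpl.weights.mean() == pytest.approx(0.0, abs=1e-12)

    def test_leave_one_out_shift_matches_closed_form(self, rng):
        base = rng.normal(size=12)
        maps = [base.copy() for _ in range(4)]
        delta = np.zeros(12)
        delta[3] = 2.0
        maps[0] = base + delta  # one perturbed subject
        erps = self._cohort(maps)
        ids = ["p", "a", "b", "c"]
        # template excluding the perturbed subject = normalized centred base
        loo = build_templates(erps, ids, leave_out="p")
        t = -0.5 + np.arange(2048) / FS
        w = (t >= 0.244 - 0.02) & (t < 0.244 + 0.02)
        profile = np.exp(-((t - 0.244) ** 2) / (2 * 0.04**2))[w].mean()
        expected = (base * profile) - (base * profile).mean()
        expected /= np.linalg.norm(expected)
        assert np.allclose(loo[0].weights, expected, atol=1e-9)
        # full template shifts by delta/n centred-normalized
        full = build_templates(erps, ids)
        mean_map = (base + delta / 4) * profile
        exp_full = mean_map - mean_map.mean()
        exp_full /= np.linalg.norm(exp_full)
        assert np.allclose(full[0].weights, exp_full, atol=1e-9)

    def test_insufficient_subjects_raises(self, rng):
        erps = self._cohort(rng.normal(size=(2, 12)))
        with pytest.raises(ValueError):
            build_templates(erps, ["a", "b"], leave_out="a")


class TestProjection:
    def _setup(self, rng):
        w = rng.normal(size=16)
        w -= w.mean()
        w /= np.linalg.norm(w)
        labels = tuple(f"E{i}" for i in range(16))
        from nvcouple.eeg import TemplateMap

        return labels, TemplateMap("P2", labels, w)

    def test_proportional_map_similarity_one(self, rng):
        labels, tpl = self._setup(rng)
        v = np.outer(tpl.weights, np.full(2048, 3.0))  # positive scale
        erp = SubjectERP(FS, labels, (-0.5, 3.5), v, 1)
        sim, coef = project_templates(erp, [tpl])
        assert np.allclose(sim, 1.0)
        assert np.allclose(coef, 1.0)

    def test_orthogonal_map_similarity_zero(self, rng):
        labels, tpl = self._setup(rng)
        v = rng.normal(size=16)
        v -= v.mean()
        v -= (v @ tpl.weights) * tpl.weights  # centred-orthogonal
        erp = SubjectERP(FS, labels, (-0.5, 3.5), np.outer(v, np.ones(2048)), 1)
        sim, _ = project_templates(erp, [tpl])
        assert np.max(np.abs(sim)) < 1e-9

    def test_negated_map_similarity_minus_one(self, rng):
        labels, tpl = self._setup(rng)
        erp = SubjectERP(FS, labels, (-0.5, 3.5), np.outer(-tpl.weights, np.ones(2048)), 1)
        sim, coef = project_templates(erp, [tpl])
        assert np.allclose(sim, -1.0) and np.allclose(coef, -1.0)

    def test_low_electrode_overlap_raises(self, rng):
        labels, tpl = self._setup(rng)
        v = np.outer(tpl.weights, np.ones(2048))
        v[: 8] = np.nan  # half the montage missing
        erp = SubjectERP(FS, labels, (-0.5, 3.5), v, 1)
        with pytest.raises(ValueError, match="overlap"):
            project_templates(erp, [tpl])


def test_projection_of_healthy_grand_average_near_one(montage, schedule_1, noiseless_params):
    """The healthy grand average projected on its own full-cohort template
    scores ~1 at the peaks (noiseless synthetic cohort)."""
    from nvcouple.eeg import eeg_subject_pipeline
    from nvcouple.synthetic import simulate_eeg

    erps = []
    for seed in (0, 1, 2):
        rec = simulate_eeg(noiseless_params, schedule_1, montage, seed=seed)
        erps.append(eeg_subject_pipeline(rec, schedule_1))
    templates = build_templates(erps)
    grand = SubjectERP(
        FS, erps[0].labels, erps[0].window_s,
        np.mean([e.voltage for e in erps], axis=0), len(erps),
    )
    sim, coef = project_templates(grand, templates)
    t_ms = grand.times() * 1e3
    for p, lat in enumerate((244.0, 378.0, 576.0)):
        at_peak = sim[p, np.argmin(np.abs(t_ms - lat))]
        assert at_peak > 0.98
    assert np.all(coef[:, 0] > 0.5)  # window means stay strongly positive


def test_interpolated_map_matches_electrodes_at_their_sites(montage, rng):
    """Thin-plate interpolation is exact at the electrode positions."""
    from nvcouple.eeg import interpolate_map

    vals = rng.normal(size=montage.n_electrodes)
    xx, yy, zz = interpolate_map(vals, montage.positions, grid_n=48)
    from scipy.interpolate import RBFInterpolator

    rbf = RBFInterpolator(montage.positions, vals, kernel="thin_plate_spline")
    assert np.allclose(rbf(montage.positions), vals, atol=1e-8)
    assert np.isnan(zz[0, 0])  # corners lie outside the head
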