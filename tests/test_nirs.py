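"""fNIRS pipeline: MBLL conversion, StO2, z-rejection, filtering,
segmentation and AUC summaries."""

import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

from nvcouple.nirs import (
    DPF_DEFAULT,
    EXTINCTION_UM_CM,
    HbTimeSeries,
    BlockEpochSet,
    bandpass_nirs,
    compute_sto2,
    forward_intensity,
    mbll_convert,
    reject_blocks,
    segment_and_correct,
    subject_response,
    znormalize,
)
from nvcouple.paradigm import build_paradigm
from nvcouple.synthetic import RawIntensityRecording

FS = 9.1912


def _raw(intensity, t_start=0.0):
    n_ch = intensity.shape[0]
    return RawIntensityRecording(
        sampling_rate_hz=FS,
        wavelengths_nm=(690, 830),
        channel_ids=[f"ch{i}" for i in range(n_ch)],
        intensity=intensity,
        t_start_s=t_start,
    )


class TestMBLL:
    def test_constant_intensity_gives_zero_concentration(self):
        raw = _raw(np.full((3, 2, 100), 5e5))
        conc = mbll_convert(raw)
        assert np.allclose(conc.hbo_uM, 0) and np.allclose(conc.hb_uM, 0)

    def test_round_trip_known_concentrations(self):
        # +1.0 µM HbO, -0.3 µM Hb step in the middle of the recording
        n = 400
        hbo = np.zeros(n)
        hbo[150:250] = 1.0
        hb = np.zeros(n)
        hb[150:250] = -0.3
        hbo -= hbo.mean()
        hb -= hb.mean()
        intens = np.stack(
            [forward_intensity(hbo, hb, wl, 1e6, 1.5, DPF_DEFAULT) for wl in (690, 830)]
        )[None]
        conc = mbll_convert(_raw(intens))
        assert np.max(np.abs(conc.hbo_uM[0] - hbo)) < 1e-6
        assert np.max(np.abs(conc.hb_uM[0] - hb)) < 1e-6

    def test_halved_intensity_solves_two_by_two_system(self):
        n = 101
        intens = np.full((1, 2, n), 1e6)
        intens[0, :, 50] = 5e5  # one sample at half intensity, both wavelengths
        conc = mbll_convert(_raw(intens), reference="mean")
        d_od = np.log10(2.0)
        path = 1.5 * DPF_DEFAULT
        e = np.array(
            [[EXTINCTION_UM_CM[w]["hbo"], EXTINCTION_UM_CM[w]["hb"]] for w in (690, 830)]
        )
        expected = np.linalg.solve(e * path, [d_od, d_od])
        # subtract the reference offset of the remaining samples
        ref = np.array([conc.hbo_uM[0, 0], conc.hb_uM[0, 0]])
        got = np.array([conc.hbo_uM[0, 50], conc.hb_uM[0, 50]]) - ref
        assert np.allclose(got, expected, rtol=1e-6)

    def test_nonpositive_intensity_names_channel(self):
        intens = np.full((2, 2, 10), 1e6)
        intens[1, 0, 3] = 0.0
        with pytest.raises(ValueError, match="ch1"):
            mbll_convert(_raw(intens))


class TestStO2:
    @pytest.mark.parametrize(
        "hbo,hb,expected", [(30, 10, 0.75), (17, 17, 0.5), (5, 0, 1.0)]
    )
    def test_formula(self, hbo, hb, expected):
        assert compute_sto2(hbo, hb) == pytest.approx(expected)

    def test_undefined_at_zero_total(self):
        with pytest.raises(ValueError):
            compute_sto2(0.0, 0.0)

    def test_elementwise(self):
        out = compute_sto2(np.array([30.0, 17.0]), np.array([10.0, 17.0]))
        assert np.allclose(out, [0.75, 0.5])


class TestZNormalize:
    def _series(self, data):
        return HbTimeSeries(FS, [f"ch{i}" for i in range(data.shape[0])], data, data.copy())

    def test_unit_sd_zero_mean(self, rng):
        z = znormalize(self._series(rng.normal(2.0, 3.0, size=(4, 500))))
        assert np.allclose(z.hbo_uM.std(axis=1), 1.0, atol=1e-12)
        assert np.allclose(z.hbo_uM.mean(axis=1), 0.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(2, 300))
        za = znormalize(self._series(x))
        zb = znormalize(self._series(3.7 * x + 11.0))
        assert np.allclose(za.hbo_uM, zb.hbo_uM)

    def test_constant_channel_raises(self):
        x = np.ones((2, 100))
        with pytest.raises(ValueError, match="ch0"):
            znormalize(self._series(x))


class TestRejectBlocks:
    def _z_series(self, n_blocks, excursions=()):
        """Zero signal with unit-variance noise stand-in: direct z values."""
        sch = build_paradigm(n_blocks, seed=0)
        n = int(np.ceil((10 + sch.duration_s) * FS))
        z = np.zeros((2, n))
        t = -10 + np.arange(n) / FS
        for ch, t_exc, val in excursions:
            idx = np.argmin(np.abs(t - t_exc))
            z[ch, idx] = val
        series = HbTimeSeries(FS, ["a", "b"], z, np.zeros_like(z), t_start_s=-10.0)
        return series, sch

    def test_all_subthreshold_retained(self):
        series, sch = self._z_series(3)
        assert reject_blocks(series, sch).all()

    def test_single_excursion_rejects_only_its_block(self):
        series, sch = self._z_series(3, excursions=[(1, 65.0, 10.0)])  # block 1 window
        mask = reject_blocks(series, sch)
        assert list(mask) == [True, False, True]

    def test_excursion_outside_all_windows_is_harmless(self):
        # >25 s after block 0 onset and >5 s before block 1 onset
        series, sch = self._z_series(2, excursions=[(0, 40.0, 10.0)])
        assert reject_blocks(series, sch).all()

    def test_threshold_monotonicity(self):
        series, sch = self._z_series(4, excursions=[(0, 5.0, 3.0), (1, 125.0, 5.0)])
        retained = [reject_blocks(series, sch, threshold=th).sum() for th in (6, 4, 2, 1)]
        assert retained == sorted(retained, reverse=True)
        assert all(
            a >= b for a, b in zip(retained, retained[1:])
        )


class TestBandpass:
    def _series(self, x):
        return HbTimeSeries(FS, ["ch0"], x[None], x[None].copy())

    def test_dc_removed(self):
        out = bandpass_nirs(self._series(np.full(2000, 5.0)))
        assert abs(out.hbo_uM.mean()) < 1e-3

    @staticmethod
    def _tone_amplitude(y, t, freq):
        """Amplitude of the ``freq`` component by complex demodulation,
        insensitive to the slowly decaying filtfilt edge transient."""
        z = y * np.exp(-2j * np.pi * freq * t)
        return 2 * np.abs(z.mean())

    def test_cardiac_attenuated_below_one_percent(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 2.733 * t)  # 164 BPM
        out = bandpass_nirs(self._series(x))
        # analytic zero-phase (squared) magnitude response is deep in the stopband
        sos = butter(6, (0.03, 0.5), btype="bandpass", fs=FS, output="sos")
        _, h = sosfreqz(sos, worN=[2.733], fs=FS)
        assert np.abs(h[0]) ** 2 < 0.01
        amp = self._tone_amplitude(out.hbo_uM[0, 500:-500], t[500:-500], 2.733)
        assert amp < 0.01

    def test_passband_tone_preserved(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        out = bandpass_nirs(self._series(x))
        amp = self._tone_amplitude(out.hbo_uM[0, 1000:-1000], t[1000:-1000], 0.1)
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            bandpass_nirs(self._series(np.zeros(10)))


class TestSegmentation:
    def test_pure_line_annihilated(self):
        sch = build_paradigm(1, seed=0)
        n = int(np.ceil((10 + 60) * FS))
        t = -10 + np.arange(n) / FS
        x = (2.5 * t + 1.0)[None]
        series = HbTimeSeries(FS, ["ch0"], x, x.copy(), t_start_s=-10.0)
        ep = segment_and_correct(series, sch)
        assert np.max(np.abs(ep.hbo)) < 1e-9

    def test_baseline_window_zero_mean(self):
        sch = build_paradigm(1, seed=0)
        n = int(np.ceil(70 * FS))
        t = -10 + np.arange(n) / FS
        x = np.where((t >= 0) & (t < 20), 3.0, 0.0)[None]
        series = HbTimeSeries(FS, ["ch0"], x, x.copy(), t_start_s=-10.0)
        ep = segment_and_correct(series, sch)
        tt = ep.times()
        base = ep.hbo[0, 0, (tt >= -5) & (tt < 0)]
        assert abs(base.mean()) < 1e-9

    def test_epoch_sample_count(self, schedule_1):
        n = int(np.ceil(70 * FS))
        x = np.zeros((1, n))
        x[0, ::7] = 0.1
        series = HbTimeSeries(FS, ["ch0"], x, x.copy(), t_start_s=-10.0)
        ep = segment_and_correct(series, schedule_1)
        assert ep.hbo.shape[-1] == 275  # floor(30 s x 9.1912 Hz)

    def test_no_retained_blocks_raises(self, schedule_1):
        n = int(np.ceil(70 * FS))
        x = np.zeros((1, n))
        series = HbTimeSeries(FS, ["ch0"], x, x.copy(), t_start_s=-10.0)
        with pytest.raises(ValueError, match="no retained blocks"):
            segment_and_correct(series, schedule_1, retained_mask=np.array([False]))


class TestSubjectResponse:
    def _epochs(self, mean_trace, fs=10.0):
        """Single-epoch set with a prescribed mean trace on a clean grid."""
        n = int(30 * fs)
        arr = np.tile(mean_trace, (1, 1, 1))
        return BlockEpochSet(
            sampling_rate_hz=fs,
            channel_ids=["ch0"],
            window_s=(-5.0, 25.0),
            hbo=arr,
            hb=arr.copy(),
            retained_mask=np.array([True]),
        )

    def test_rectangle_auc(self):
        fs = 10.0
        t = -5 + np.arange(int(30 * fs)) / fs
        y = np.where((t >= 0) & (t < 10), 1.0, 0.0)[None]
        resp = subject_response(self._epochs(y, fs))
        assert resp.auc_uM_s[0] == pytest.approx(10.0, abs=0.11)  # edge ramp ~1 sample

    def test_zero_response_zero_auc(self):
        resp = subject_response(self._epochs(np.zeros((1, 300))))
        assert resp.auc_uM_s[0] == 0.0

    def test_triangle_auc_closed_form(self):
        fs = 10.0
        t = -5 + np.arange(int(30 * fs)) / fs
        h = 2.0
        y = np.where((t >= 0) & (t <= 10), h * (1 - np.abs(t - 5) / 5), 0.0)[None]
        resp = subject_response(self._epochs(y, fs))
        # apex and window edges lie on the grid -> trapezoid is exact
        assert resp.auc_uM_s[0] == pytest.approx(5 * h, rel=1e-9)

    def test_auc_window_validation(self):
        with pytest.raises(ValueError):
            subject_response(self._epochs(np.zeros((1, 300))), auc_window_s=(0.0, 30.0))


def test_pipeline_linearity_in_amplitude(layout):
    """Scaling the noise-free input concentrations scales the AUC."""
    from nvcouple.nirs import nirs_subject_pipeline
    from nvcouple.synthetic import SubjectParams, simulate_nirs

    sch = build_paradigm(3, seed=1)
    aucs = []
    for amp in (0.5, 1.0):
        p = SubjectParams(hbo_peak_amplitude_uM=amp).noiseless()
        rec = simulate_nirs(p, sch, layout, seed=0)
        resp = nirs_subject_pipeline(rec, sch, layout)
        aucs.append(resp.auc_uM_s)
    assert np.allclose(aucs[1], 2 * aucs[0], rtol=1e-6)
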