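import numpy as np
import pytest

from nirsfc.config import PipelineConfig
from nirsfc.io import RawRecording
from nirsfc.montage import SubjectMeta, scale_channel_distances
from nirsfc.preprocess import (
    ODSeries,
    PIPELINE_STAGES,
    bandpass,
    concat_resample,
    mbll_forward,
    mbll_invert,
    normalize_segment,
    od_from_intensity,
    run_subject_pipeline,
    total_hb,
    wavelet_motion_correct,
)

FS = 10.17


class TestOpticalDensity:
    def test_constant_intensity_gives_zero(self):
        rec = RawRecording(SubjectMeta("c"), np.full((100, 20, 2), 2.5))
        assert np.allclose(od_from_intensity(rec).od, 0.0)

    def test_inverse_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.01, (300, 20, 2))
        x -= x.mean(axis=0, keepdims=True)
        intensity = np.exp(-x)
        intensity /= intensity.mean(axis=0, keepdims=True)
        rec = RawRecording(SubjectMeta("c"), intensity)
        od = od_from_intensity(rec).od
        assert np.abs(od - od.mean(axis=0) - (x - x.mean(axis=0))).max() < 1e-12

    def test_nonpositive_intensity_rejected(self):
        bad = np.ones((50, 20, 2))
        bad[10, 3, 0] = 0.0
        with pytest.raises(ValueError):
            od_from_intensity(RawRecording(SubjectMeta("c"), bad))


class TestWaveletDespike:
    def test_zero_signal_unchanged(self):
        out = wavelet_motion_correct(np.zeros(int(60 * FS)), FS)
        assert np.allclose(out, 0.0)

    def test_smooth_sinusoid_barely_changed(self):
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        out = wavelet_motion_correct(x, FS)
        assert np.sqrt(np.mean((out - x) ** 2)) / x.std() < 0.05

    def test_spike_removed_signal_preserved(self):
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        i0 = len(x) // 2
        i1 = i0 + int(0.5 * FS)
        y = x.copy()
        y[i0:i1] += 10 * x.std()
        out = wavelet_motion_correct(y, FS)
        peak_reduction = 1 - (out[i0:i1] - x[i0:i1]).max() / (10 * x.std())
        assert peak_reduction >= 0.8
        off = np.ones(len(x), bool)
        off[i0 - 30:i1 + 30] = False
        rms_change = np.sqrt(np.mean((out[off] - x[off]) ** 2)) / x.std()
        assert rms_change < 0.10

    def test_output_length_preserved(self):
        for n in (173, 1024, 3001):
            out = wavelet_motion_correct(np.random.default_rng(1).normal(size=n), FS)
            assert out.shape == (n,)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            wavelet_motion_correct(np.zeros(8), FS)


class TestMBLL:
    def test_zero_od_gives_zero_conc(self, montage):
        od = ODSeries(np.zeros((100, 20, 2)), FS, tuple(range(1, 21)))
        conc = mbll_invert(od, montage)
        assert np.allclose(conc.data["hbo"], 0.0)
        assert np.allclose(conc.data["hbr"], 0.0)

    def test_forward_inverse_round_trip(self, montage):
        rng = np.random.default_rng(1)
        hbo = rng.normal(0, 2.0, (400, 20))
        hbr = rng.normal(0, 1.0, (400, 20))
        od = mbll_forward(hbo, hbr, montage)
        conc = mbll_invert(ODSeries(od, FS, tuple(range(1, 21))), montage)
        assert np.abs(conc.data["hbo"] - hbo).max() < 1e-9
        assert np.abs(conc.data["hbr"] - hbr).max() < 1e-9

    def test_doubling_distance_halves_concentration(self, montage):
        rng = np.random.default_rng(2)
        od = ODSeries(rng.normal(0, 1e-3, (200, 20, 2)), FS,
                      tuple(range(1, 21)))
        conc1 = mbll_invert(od, montage)
        doubled = scale_channel_distances(
            montage, 2 * montage.reference_circumference_mm)
        conc2 = mbll_invert(od, doubled)
        assert np.allclose(conc2.data["hbo"], conc1.data["hbo"] / 2)

    def test_singular_extinction_rejected(self, montage):
        cfg = PipelineConfig()
        cfg.extinction = {760.0: {"hbo": 1.0, "hbr": 1.0},
                          850.0: {"hbo": 1.0, "hbr": 1.0}}
        od = ODSeries(np.zeros((10, 20, 2)), FS, tuple(range(1, 21)))
        with pytest.raises(ValueError, match="singular"):
            mbll_invert(od, montage, cfg)


class TestBandpass:
    def test_passband_amplitude_retained(self):
        t = np.arange(int(300 * FS)) / FS
        x = np.sin(2 * np.pi * 0.04 * t)
        assert bandpass(x, FS).std() / x.std() >= 0.90

    def test_stopband_attenuation(self):
        t = np.arange(int(300 * FS)) / FS
        x = np.sin(2 * np.pi * 0.5 * t)
        atten_db = 20 * np.log10(bandpass(x, FS).std() / x.std())
        assert atten_db <= -20

    def test_dc_removed(self):
        out = bandpass(np.full(int(300 * FS), 7.0), FS)
        assert abs(out.mean()) < 1e-6 * 7.0

    def test_rate_check(self):
        with pytest.raises(ValueError):
            bandpass(np.ones(100), rate=0.1)


class TestNormalizationAndHbT:
    def test_total_hb_is_elementwise_sum(self):
        from nirsfc.preprocess import ConcSeries

        conc = ConcSeries(
            {"hbo": np.array([[1.0]]), "hbr": np.array([[-0.3]])},
            FS, (1,))
        out = total_hb(conc)
        assert out.data["hbt"][0, 0] == pytest.approx(0.7)

    def test_total_hb_length_mismatch_rejected(self):
        from nirsfc.preprocess import ConcSeries

        conc = ConcSeries(
            {"hbo": np.zeros((5, 1)), "hbr": np.zeros((4, 1))}, FS, (1,))
        with pytest.raises(ValueError):
            total_hb(conc)

    def test_normalize_moments_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(3.0, 2.0, (500, 4))
        out, valid = normalize_segment(x)
        assert valid.all()
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)
        out2, _ = normalize_segment(5.0 * x - 11.0)
        assert np.allclose(out, out2, atol=1e-9)

    def test_normalize_idempotent(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(300, 3))
        once, _ = normalize_segment(x)
        twice, _ = normalize_segment(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_constant_channel_flagged_not_nan(self):
        x = np.column_stack([np.ones(100), np.random.default_rng(5).normal(size=100)])
        out, valid = normalize_segment(x)
        assert not valid[0] and valid[1]
        assert np.isfinite(out).all()


class TestConcatResample:
    def test_length_arithmetic(self):
        x = np.zeros((1017, 3))
        out, _ = concat_resample([x], FS, 4.0)
        assert abs(out.shape[0] - 400) <= 1

    def test_waveform_preserved(self):
        t = np.arange(int(300 * FS)) / FS
        x = np.sin(2 * np.pi * 0.05 * t)[:, None]
        out, _ = concat_resample([x], FS, 4.0)
        mid = slice(out.shape[0] // 4, 3 * out.shape[0] // 4)
        assert out[mid].std() * np.sqrt(2) == pytest.approx(1.0, abs=0.02)

    def test_single_segment_boundary(self):
        x = np.zeros((500, 2))
        _, boundaries = concat_resample([x], FS, 4.0)
        assert boundaries == (0,)

    def test_boundaries_remapped(self):
        segs = [np.zeros((1017, 1)), np.zeros((2034, 1))]
        _, boundaries = concat_resample(segs, FS, 4.0)
        assert boundaries == (0, 400)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            concat_resample([], FS, 4.0)


class TestSubjectPipeline:
    def test_clean_recording_fully_retained(self, clean_recording, montage):
        rec, truth, _ = clean_recording
        res = run_subject_pipeline(rec, montage)
        assert res.report.decision == "keep"
        assert res.valid_channels.all()
        assert len(res.segments.intervals) == 1
        assert res.conc.data["hbt"].shape[1] == 20
        assert res.conc.rate == 4.0

    def test_provenance_stage_order(self, clean_recording, montage):
        rec, _, _ = clean_recording
        res = run_subject_pipeline(rec, montage)
        stages = [p["stage"] for p in res.provenance]
        assert tuple(stages) == PIPELINE_STAGES

    def test_dead_channels_invalid(self, montage):
        from nirsfc.synth import SimParams, plan_ground_truth, sample_cohort, simulate_recording

        params = SimParams(n_subjects=1, duration_range=(300.0, 300.0),
                           dead_channel_prob=0.0, motion_epoch_rate=0.0,
                           spike_rate=0.0)
        meta = sample_cohort(params, 31)[0]
        truth = plan_ground_truth(meta, params, 31, montage=montage)
        truth.dead_channels = {5, 12}
        rec = simulate_recording(meta, truth, params, 31, montage)
        res = run_subject_pipeline(rec, montage)
        assert res.report.decision == "keep"
        idx5 = rec.channel_ids.index(5)
        idx12 = rec.channel_ids.index(12)
        assert not res.valid_channels[idx5]
        assert not res.valid_channels[idx12]
        assert res.valid_channels.sum() == 18

    def test_no_cardiac_is_clean_exclusion(self, montage):
        from nirsfc.synth import SimParams, plan_ground_truth, sample_cohort, simulate_recording

        params = SimParams(n_subjects=1, duration_range=(200.0, 200.0),
                           cardiac_amp=0.0, resp_amp=0.0,
                           motion_epoch_rate=0.0, spike_rate=0.0)
        meta = sample_cohort(params, 33)[0]
        truth = plan_ground_truth(meta, params, 33, montage=montage)
        rec = simulate_recording(meta, truth, params, 33, montage)
        res = run_subject_pipeline(rec, montage)
        assert res.report.decision == "exclude"
        assert res.report.reason == "no_cardiac_channels"
        assert res.conc is None

    def test_heavy_motion_is_clean_exclusion(self, montage):
        from nirsfc.synth import SimParams, plan_ground_truth, sample_cohort, simulate_recording

        params = SimParams(n_subjects=1, duration_range=(200.0, 200.0),
                           motion_epoch_rate=0.0, spike_rate=0.0)
        meta = sample_cohort(params, 35)[0]
        truth = plan_ground_truth(meta, params, 35, montage=montage)
        # one long epoch leaves < 50 s clean on either side
        truth.motion_schedule = [(45.0, 170.0, "epoch")]
        rec = simulate_recording(meta, truth, params, 35, montage)
        res = run_subject_pipeline(rec, montage)
        # the epoch may also suppress cardiac power enough to fail
        # screening outright; any exclusion reason is a clean terminal state
        assert res.report.decision == "exclude"
        assert res.conc is None
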