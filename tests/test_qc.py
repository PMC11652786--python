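import numpy as np
import pytest

from nirsfc.config import PipelineConfig
from nirsfc.qc import (
    QualityTimeline,
    apply_exclusion,
    build_sample_mask,
    cardiac_presence,
    extract_segments,
    remainder_proportion,
    windowed_sci_psp,
)

from _oracles import run_length_segments

FS = 10.17


def _one_over_f(n, rng, fs=FS, alpha=1.0):
    w = rng.standard_normal(n)
    F = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, 1 / fs)
    f[0] = f[1]
    return np.fft.irfft(F / f ** (alpha / 2), n)


class TestCardiacPresence:
    def test_sinusoid_with_noise_retained(self):
        rng = np.random.default_rng(0)
        n = int(150 * FS)
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * 2.2 * t) + rng.standard_normal(n) / np.sqrt(10)
        retained, ratio = cardiac_presence(x, FS)
        assert retained and ratio > 10

    def test_one_over_f_null_rarely_flags(self):
        """Monte-Carlo: under a 1/f spectrum the peak ratio stays below the
        k=3 default in at least 95% of 150-s runs."""
        rng = np.random.default_rng(1)
        n = int(150 * FS)
        below = sum(
            cardiac_presence(_one_over_f(n, rng), FS)[1] < 3.0
            for _ in range(200)
        )
        assert below >= 0.95 * 200

    def test_white_noise_flagged(self):
        rng = np.random.default_rng(2)
        retained, _ = cardiac_presence(rng.standard_normal(int(150 * FS)), FS)
        assert not retained

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            cardiac_presence(np.zeros(100), FS)


class TestWindowedSciPsp:
    def _od(self, x760, x850):
        return np.stack([x760[:, None], x850[:, None]], axis=2)

    def test_identical_cardiac_gives_unit_sci(self):
        t = np.arange(int(60 * FS)) / FS
        card = np.sin(2 * np.pi * 2.0 * t)
        tl = windowed_sci_psp(self._od(card, card), FS)
        assert np.all(tl.sci > 1 - 1e-9)
        assert np.all(tl.psp > 0.1)

    def test_antiphase_gives_minus_one(self):
        t = np.arange(int(60 * FS)) / FS
        card = np.sin(2 * np.pi * 1.5 * t)
        tl = windowed_sci_psp(self._od(card, -card), FS)
        assert np.all(tl.sci < -1 + 1e-9)

    def test_independent_noise_sci_small(self):
        rng = np.random.default_rng(3)
        n = int(120 * FS)
        tl = windowed_sci_psp(
            self._od(rng.standard_normal(n), rng.standard_normal(n)), FS)
        assert np.mean(np.abs(tl.sci) < 0.5) >= 0.95
        assert abs(tl.sci.mean()) < 0.1

    def test_sci_symmetric_and_affine_invariant(self):
        rng = np.random.default_rng(4)
        n = int(60 * FS)
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        tl_ab = windowed_sci_psp(self._od(a, b), FS)
        tl_ba = windowed_sci_psp(self._od(b, a), FS)
        assert np.allclose(tl_ab.sci, tl_ba.sci, atol=1e-12)
        tl_scaled = windowed_sci_psp(self._od(3.5 * a + 7.0, b), FS)
        assert np.allclose(tl_ab.sci, tl_scaled.sci, atol=1e-9)

    def test_window_grid_geometry(self):
        n = int(30 * FS)
        tl = windowed_sci_psp(self._od(np.ones(n), np.ones(n)), FS)
        hops = np.diff(tl.window_starts)
        assert np.allclose(hops, 1.0)
        lengths = tl.window_samples[:, 1] - tl.window_samples[:, 0]
        assert np.all(lengths == round(5 * FS))

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            windowed_sci_psp(self._od(np.ones(10), np.ones(10)), FS)


class TestSampleMask:
    def _timeline(self, win_ok, n_samples, nch=4):
        starts = np.arange(len(win_ok), dtype=float)
        spans = np.array([
            [int(round(s * FS)), int(round(s * FS)) + int(round(5 * FS))]
            for s in starts
        ])
        sci = np.where(np.asarray(win_ok)[:, None], 1.0, -1.0) * np.ones(nch)
        psp = np.where(np.asarray(win_ok)[:, None], 1.0, 0.0) * np.ones(nch)
        return QualityTimeline(starts, spans, sci, psp, np.ones(nch, bool))

    def test_all_windows_pass(self):
        n = int(30 * FS)
        tl = self._timeline([True] * 26, n)
        assert build_sample_mask(tl, n, FS).all()

    def test_single_bad_window_blanks_exactly_its_cover(self):
        n = int(30 * FS)
        win_ok = [True] * 26
        win_ok[10] = False
        tl = self._timeline(win_ok, n)
        mask = build_sample_mask(tl, n, FS)
        # brute-force oracle: a sample is good iff all covering windows good
        expected = np.ones(n, bool)
        for ok, (i0, i1) in zip(win_ok, tl.window_samples):
            if not ok:
                expected[i0:i1] = False
        assert np.array_equal(mask, expected)
        assert not mask[tl.window_samples[10][0]:tl.window_samples[10][1]].any()

    def test_vacuous_thresholds_pass_everything(self):
        n = int(30 * FS)
        rng = np.random.default_rng(0)
        tl = QualityTimeline(
            np.arange(26, dtype=float),
            np.array([[int(round(s * FS)), int(round(s * FS)) + 50]
                      for s in range(26)]),
            rng.uniform(-1, 1, (26, 4)),
            rng.uniform(0, 1, (26, 4)),
            np.ones(4, bool),
        )
        cfg = PipelineConfig(sci_threshold=-1.0, psp_threshold=0.0)
        assert build_sample_mask(tl, n, FS, cfg).all()

    def test_no_retained_channels_rejected(self):
        tl = self._timeline([True] * 5, int(10 * FS))
        tl.retained = np.zeros(4, bool)
        with pytest.raises(ValueError):
            build_sample_mask(tl, int(10 * FS), FS)


class TestSegmentExtraction:
    def test_all_good_is_one_segment(self):
        n = int(60 * FS)
        segs = extract_segments(np.ones(n, bool), FS)
        assert segs.intervals == ((0, n),)
        assert segs.total_seconds == pytest.approx(60.0, abs=0.1)

    def test_below_minimum_dropped(self):
        n = int(49 * FS)
        assert extract_segments(np.ones(n, bool), FS).intervals == ()

    def test_brief_gap_bridged(self):
        good1, bad, good2 = int(40 * FS), int(1.5 * FS), int(40 * FS)
        mask = np.r_[np.ones(good1, bool), np.zeros(bad, bool),
                     np.ones(good2, bool)]
        segs = extract_segments(mask, FS)
        assert len(segs.intervals) == 1
        assert segs.total_seconds == pytest.approx(
            (good1 + bad + good2) / FS, abs=1e-9)

    def test_two_second_gap_not_bridged(self):
        # ceil so the gap is >= 2 s after sample rounding
        good, bad = int(60 * FS), int(np.ceil(2.0 * FS))
        mask = np.r_[np.ones(good, bool), np.zeros(bad, bool),
                     np.ones(good, bool)]
        segs = extract_segments(mask, FS)
        assert len(segs.intervals) == 2

    def test_matches_run_length_oracle_on_random_masks(self):
        """Property: implementation equals the brute-force run-length oracle
        on 1000 random masks."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(50, 2000))
            rate = float(rng.uniform(4.0, 12.0))
            p = rng.uniform(0.2, 0.95)
            mask = rng.random(n) < p
            min_seg = float(rng.uniform(1.0, 20.0))
            gap = float(rng.uniform(0.1, 3.0))
            got = extract_segments(mask, rate, min_seg, gap).intervals
            want = tuple(run_length_segments(mask, rate, min_seg, gap))
            assert got == want


class TestExclusion:
    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(7)
        n = int(200 * FS)
        nwin = 196
        starts = np.arange(nwin, dtype=float)
        spans = np.array([[int(round(s * FS)),
                           int(round(s * FS)) + int(round(5 * FS))]
                          for s in starts])
        sci = rng.uniform(-0.5, 1.0, (nwin, 6))
        psp = rng.uniform(0.0, 0.5, (nwin, 6))
        tl = QualityTimeline(starts, spans, sci, psp, np.ones(6, bool))
        totals = []
        for thr in (0.0, 0.1, 0.3, 0.6):
            cfg = PipelineConfig(sci_threshold=thr)
            mask = build_sample_mask(tl, n, FS, cfg)
            totals.append(extract_segments(mask, FS).total_seconds)
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_short_total_excluded(self):
        from nirsfc.qc import SegmentSet

        segs = SegmentSet(((0, int(140 * FS)),), FS)
        rep = apply_exclusion("d1", 600.0, np.ones(20, bool), segs)
        assert rep.decision == "exclude"
        assert rep.reason == "total_below_min"

    def test_no_cardiac_channels(self):
        from nirsfc.qc import SegmentSet

        rep = apply_exclusion("d2", 600.0, np.zeros(20, bool),
                              SegmentSet((), FS))
        assert rep.reason == "no_cardiac_channels"

    def test_no_segments(self):
        from nirsfc.qc import SegmentSet

        rep = apply_exclusion("d3", 600.0, np.ones(20, bool),
                              SegmentSet((), FS))
        assert rep.reason == "no_segments"

    @pytest.mark.parametrize("total,post,expected", [
        (543.32, 252.84, 47),
        (485.82, 475.69, 98),
        (900.86, 566.43, 63),
    ])
    def test_remainder_proportion_reference_rows(self, total, post, expected):
        assert remainder_proportion(total, post) == expected
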