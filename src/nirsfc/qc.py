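"""Signal-quality screening and motion-free segmentation.

Three gates, in order:

1. cardiac presence — a channel is kept only if its optical-density spectrum
   shows a clear cardiac peak (automated spectral surrogate for manual
   frequency-domain inspection);
2. windowed scalp coupling index (SCI) and peak spectral power (PSP) in 5-s
   windows with 4-s overlaps over the 60-210 bpm cardiac band;
3. motion-free segments of at least 50 s (brief <2 s artifacts bridged),
   with datasets excluded when no segment survives or the total is below
   2.5 min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import PipelineConfig


@dataclass
class QualityTimeline:
    """Windowed per-channel quality traces.

    ``sci``/``psp`` have shape (n_windows, n_channels); windows are
    ``window_length`` seconds long on a 1-s hop grid.
    """

    window_starts: np.ndarray          # seconds
    window_samples: np.ndarray         # (n_windows, 2) [start, stop) sample idx
    sci: np.ndarray
    psp: np.ndarray
    retained: np.ndarray               # bool per channel


@dataclass
class SegmentSet:
    """Disjoint, sorted motion-free intervals [start, stop) in samples."""

    intervals: tuple[tuple[int, int], ...]
    rate: float

    @property
    def total_seconds(self) -> float:
        return sum(i1 - i0 for i0, i1 in self.intervals) / self.rate


@dataclass
class ExclusionReport:
    dataset_id: str
    decision: str                      # keep | exclude
    reason: str                        # ok | no_cardiac_channels | no_segments | total_below_min
    remainder_proportion: float        # percent of recording surviving segmentation

    def __post_init__(self) -> None:
        if (self.decision == "exclude") != (self.reason != "ok"):
            raise ValueError("decision and reason are inconsistent")


# --------------------------------------------------------------------------
# cardiac presence screening
# --------------------------------------------------------------------------

def cardiac_presence(
    series: np.ndarray,
    rate: float,
    cardiac_band_hz: tuple[float, float] = (1.0, 3.5),
    k: float = 3.0,
) -> tuple[bool, float]:
    """Decide whether a single OD series carries a cardiac pulsation.

    The Welch spectrum is whitened by a log-log linear background fit over
    0.5-4.5 Hz (so 1/f-like physiological backgrounds do not masquerade as
    peaks); the statistic is the whitened in-band peak divided by the median
    whitened broadband power excluding the peak bin. Returns
    (retained, peak_ratio); retained iff peak_ratio >= k.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 60 * rate:
        raise ValueError("need at least 60 s of signal for cardiac screening")
    f, p = signal.welch(series, fs=rate, nperseg=min(256, series.size))
    broad = (f >= 0.5) & (f <= min(4.5, 0.99 * rate / 2))
    if broad.sum() < 8:
        raise ValueError("spectrum too coarse for cardiac screening")
    lf, lp = np.log(f[broad]), np.log(np.maximum(p[broad], 1e-300))
    slope, intercept = np.polyfit(lf, lp, 1)
    white = p[broad] / np.exp(slope * lf + intercept)
    fb = f[broad]
    inband = (fb >= cardiac_band_hz[0]) & (fb <= cardiac_band_hz[1])
    if not inband.any():
        raise ValueError("cardiac band outside the resolvable spectrum")
    peak = int(np.argmax(np.where(inband, white, -np.inf)))
    rest = np.ones_like(white, dtype=bool)
    rest[peak] = False
    ratio = float(white[peak] / np.median(white[rest]))
    return ratio >= k, ratio


def screen_channels(
    od: np.ndarray, rate: float, config: PipelineConfig | None = None
) -> np.ndarray:
    """Apply cardiac screening per channel; a channel is retained only if
    both wavelengths show the cardiac peak. ``od`` is (n, nch, 2)."""
    config = config or PipelineConfig()
    band = config.cardiac_band_hz
    # clip the screening band to what the sampling rate can resolve
    band = (band[0], min(band[1], 0.95 * rate / 2))
    nch = od.shape[1]
    retained = np.zeros(nch, dtype=bool)
    for c in range(nch):
        ok = True
        for wi in range(2):
            keep, _ = cardiac_presence(od[:, c, wi], rate, band,
                                       config.cardiac_peak_ratio)
            ok &= keep
        retained[c] = ok
    return retained


# --------------------------------------------------------------------------
# windowed SCI / PSP
# --------------------------------------------------------------------------

def _window_grid(n_samples: int, rate: float, config: PipelineConfig):
    """5-s windows on a 1-s hop (window_length − window_overlap); sample
    indices by rounding; the final partial window is discarded."""
    hop = config.window_length - config.window_overlap
    wlen = int(round(config.window_length * rate))
    starts_s, spans = [], []
    k = 0
    while True:
        t0 = k * hop
        i0 = int(round(t0 * rate))
        if i0 + wlen > n_samples:
            break
        starts_s.append(t0)
        spans.append((i0, i0 + wlen))
        k += 1
    return np.array(starts_s), np.array(spans, dtype=int).reshape(-1, 2)


def windowed_sci_psp(
    od: np.ndarray,
    rate: float,
    retained: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> QualityTimeline:
    """Windowed scalp coupling index and peak spectral power per channel.

    Both wavelength series are band-passed to the cardiac band and
    standardized within each window. SCI is their zero-lag Pearson
    correlation; PSP is the maximum of the normalized power spectrum of
    their windowed cross-correlation, restricted to the cardiac band.
    """
    config = config or PipelineConfig()
    n, nch, _ = od.shape
    if retained is None:
        retained = np.ones(nch, dtype=bool)
    starts, spans = _window_grid(n, rate, config)
    if len(starts) == 0:
        raise ValueError("recording shorter than one analysis window")

    lo, hi = config.cardiac_band_hz
    hi = min(hi, 0.95 * rate / 2)
    sos = signal.butter(3, [lo, hi], btype="band", fs=rate, output="sos")
    filtered = signal.sosfiltfilt(sos, od, axis=0)

    sci = np.zeros((len(starts), nch))
    psp = np.zeros((len(starts), nch))
    for w, (i0, i1) in enumerate(spans):
        win = filtered[i0:i1]                       # (wlen, nch, 2)
        mu = win.mean(axis=0, keepdims=True)
        sd = win.std(axis=0, keepdims=True)
        z = (win - mu) / np.where(sd > 0, sd, 1.0)
        x, y = z[:, :, 0], z[:, :, 1]
        sci[w] = (x * y).mean(axis=0)
        wlen = i1 - i0
        nfft = 2 * wlen - 1
        # cross-correlation via FFT, all channels at once
        X = np.fft.rfft(x, n=nfft, axis=0)
        Y = np.fft.rfft(y, n=nfft, axis=0)
        cc = np.fft.irfft(X * np.conj(Y), n=nfft, axis=0) / wlen
        P = np.abs(np.fft.rfft(cc, axis=0)) ** 2
        tot = P.sum(axis=0)
        P = P / np.where(tot > 0, tot, 1.0)
        freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
        inband = (freqs >= lo) & (freqs <= hi)
        psp[w] = P[inband].max(axis=0)
    return QualityTimeline(starts, spans, sci, psp, np.asarray(retained, bool))


def build_sample_mask(
    timeline: QualityTimeline,
    n_samples: int,
    rate: float,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Per-sample good/bad mask from the windowed quality traces.

    A window is good iff at least ``channel_fraction`` of retained channels
    satisfy SCI ≥ threshold and PSP ≥ threshold; a sample is good iff every
    window covering it is good (samples covered by no window stay good).
    """
    config = config or PipelineConfig()
    retained = timeline.retained
    if not retained.any():
        raise ValueError("no retained channels")
    ok = (timeline.sci[:, retained] >= config.sci_threshold) & (
        timeline.psp[:, retained] >= config.psp_threshold
    )
    frac = ok.mean(axis=1)
    win_good = frac >= config.channel_fraction
    mask = np.ones(n_samples, dtype=bool)
    for good, (i0, i1) in zip(win_good, timeline.window_samples):
        if not good:
            mask[i0:i1] = False
    return mask


# --------------------------------------------------------------------------
# segment extraction and exclusion
# --------------------------------------------------------------------------

def extract_segments(
    mask: np.ndarray,
    rate: float,
    min_segment: float = 50.0,
    gap_tolerance: float = 2.0,
) -> SegmentSet:
    """Motion-free intervals from a per-sample mask.

    Interior bad runs (bounded by good runs on both sides) strictly shorter
    than ``gap_tolerance`` seconds are bridged; good runs shorter than
    ``min_segment`` seconds are then dropped. Edge bad runs are never
    bridged. An empty SegmentSet is a valid result.
    """
    mask = np.asarray(mask, dtype=bool).copy()
    if mask.size == 0:
        raise ValueError("empty mask")
    # bridge interior short bad runs
    padded = np.concatenate([[True], mask, [True]])
    diff = np.diff(padded.astype(int))
    bad_starts = np.flatnonzero(diff == -1)
    bad_stops = np.flatnonzero(diff == 1)
    for b0, b1 in zip(bad_starts, bad_stops):
        interior = b0 > 0 and b1 < mask.size
        if interior and (b1 - b0) / rate < gap_tolerance:
            mask[b0:b1] = True
    # collect good runs
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    g0 = np.flatnonzero(diff == 1)
    g1 = np.flatnonzero(diff == -1)
    intervals = tuple(
        (int(a), int(b)) for a, b in zip(g0, g1) if (b - a) / rate >= min_segment
    )
    return SegmentSet(intervals=intervals, rate=rate)


def apply_exclusion(
    dataset_id: str,
    duration_s: float,
    retained: np.ndarray,
    segments: SegmentSet,
    config: PipelineConfig | None = None,
) -> ExclusionReport:
    """Dataset-level keep/exclude decision with the surviving-time
    proportion (percent of total recording, rounded to nearest integer)."""
    config = config or PipelineConfig()
    total = segments.total_seconds
    remainder = float(np.floor(100.0 * total / duration_s + 0.5))
    if not np.asarray(retained, bool).any():
        return ExclusionReport(dataset_id, "exclude", "no_cardiac_channels", 0.0)
    if not segments.intervals:
        return ExclusionReport(dataset_id, "exclude", "no_segments", 0.0)
    if total < config.min_total:
        return ExclusionReport(dataset_id, "exclude", "total_below_min", remainder)
    return ExclusionReport(dataset_id, "keep", "ok", remainder)


def remainder_proportion(total_scan_s: float, post_segmentation_s: float) -> int:
    """Percent of a recording surviving segmentation, rounded to nearest
    integer (half away from zero)."""
    return int(np.floor(100.0 * post_segmentation_s / total_scan_s + 0.5))
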