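"""Optical preprocessing: OD transform, wavelet despiking, modified
Beer-Lambert inversion, band-pass, HbT, per-segment normalization, and
resampling to the analysis rate.

The chain runs per motion-free segment and recombines segments at the end:

    OD -> wavelet despike -> mBLL (HbO/HbR, µM) -> 0.01-0.08 Hz band-pass
       -> HbT = HbO + HbR -> normalize (mean 0, SD 1 per segment)
       -> concatenate -> resample to 4 Hz

Absolute concentration scale cancels in the final normalization, so the
extinction table and partial pathlength factors only need to be applied
consistently (the synthetic forward model uses the same ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal

from .config import PipelineConfig
from .io import RawRecording
from .montage import Montage, scale_channel_distances
from . import qc

log = logging.getLogger(__name__)

SPECIES = ("hbo", "hbr", "hbt")


@dataclass
class ODSeries:
    """Per-channel, per-wavelength optical-density changes.

    ``od`` has shape (n_samples, n_channels, 2); ΔOD = −ln(I / mean(I)).
    """

    od: np.ndarray
    rate: float
    channel_ids: tuple[int, ...]


@dataclass
class ConcSeries:
    """Hemoglobin concentration-change series (µM before normalization).

    ``data`` maps species ("hbo", "hbr", "hbt") to arrays of shape
    (n_samples, n_channels). ``boundaries`` are the start indices of the
    concatenated segments.
    """

    data: dict[str, np.ndarray]
    rate: float
    channel_ids: tuple[int, ...]
    boundaries: tuple[int, ...] = (0,)


def od_from_intensity(rec: RawRecording) -> ODSeries:
    """ΔOD = −ln(I / mean(I)) per channel and wavelength."""
    intensity = rec.intensity
    if np.any(intensity <= 0):
        raise ValueError("intensity must be strictly positive")
    mean = intensity.mean(axis=0, keepdims=True)
    od = -np.log(intensity / mean)
    return ODSeries(od=od, rate=rec.sampling_rate, channel_ids=rec.channel_ids)


def wavelet_motion_correct(
    segment: np.ndarray,
    rate: float,
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Despike one OD segment with an IQR rule on wavelet detail coefficients.

    Per series: Daubechies decomposition to level max(4, ⌊log2 n⌋ − 4);
    within each detail level, coefficients outside
    [Q1 − c·IQR, Q3 + c·IQR] (c = ``wavelet_iqr``, default 0.6 — the stated
    equivalent of an SD threshold of 0.8) are zeroed; inverse transform.
    Output length equals input length.

    The rule is applied only to detail levels lying above the analysis band
    (level pass-band low edge at or above the band's upper corner). Motion
    spikes are sub-2-s events and live at those fine scales; at the coarse
    in-band levels the outlier bounds would clip the tails of the ordinary
    hemodynamic fluctuations themselves (≈ half their energy for
    Gaussian-like signals), systematically shrinking the very correlations
    the pipeline is meant to estimate.
    """
    config = config or PipelineConfig()
    seg = np.asarray(segment, dtype=float)
    squeeze = seg.ndim == 1
    if squeeze:
        seg = seg[:, None]
    n = seg.shape[0]
    if n < 16:
        raise ValueError("segment too short for wavelet correction (need ≥ 16 samples)")
    level = max(4, int(np.floor(np.log2(n))) - 4)
    level = min(level, pywt.dwt_max_level(n, config.wavelet))
    protect_hz = config.band[1]
    out = np.empty_like(seg)
    c = config.wavelet_iqr
    for j in range(seg.shape[1]):
        coeffs = pywt.wavedec(seg[:, j], config.wavelet, level=level, mode="symmetric")
        # coeffs[1] is the coarsest detail (level `level`), coeffs[-1] the finest
        for k, d in enumerate(coeffs[1:], start=1):
            lvl = level - k + 1
            low_edge_hz = rate / 2 ** (lvl + 1)
            if low_edge_hz < protect_hz:
                continue
            q1, q3 = np.percentile(d, [25, 75])
            iqr = q3 - q1
            mask = (d < q1 - c * iqr) | (d > q3 + c * iqr)
            d[mask] = 0.0
        out[:, j] = pywt.waverec(coeffs, config.wavelet, mode="symmetric")[:n]
    return out[:, 0] if squeeze else out


def _extinction_matrix(config: PipelineConfig, wavelengths) -> np.ndarray:
    """2x2 matrix E[λ, chromophore] in cm^-1/µM."""
    E = np.array(
        [
            [config.extinction[w]["hbo"], config.extinction[w]["hbr"]]
            for w in wavelengths
        ]
    )
    if abs(np.linalg.det(E)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    return E


def _pathlengths_cm(montage: Montage, config: PipelineConfig, channel_ids, wavelengths):
    """Effective pathlength d·PPF(λ) in cm, shape (n_channels, 2)."""
    d_cm = np.array([montage.distance_of(c) for c in channel_ids]) / 10.0
    ppf = np.array([config.ppf[w] for w in wavelengths])
    return d_cm[:, None] * ppf[None, :]


def mbll_forward(
    hbo: np.ndarray,
    hbr: np.ndarray,
    montage: Montage,
    config: PipelineConfig | None = None,
    channel_ids=tuple(range(1, 21)),
    wavelengths=(760.0, 850.0),
) -> np.ndarray:
    """Forward modified Beer-Lambert law: concentrations (µM) to ΔOD.

    ΔOD(λ) = (ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR) · d · PPF(λ).
    Shared by the synthetic generator so inversion is an exact round trip.
    """
    config = config or PipelineConfig()
    E = _extinction_matrix(config, wavelengths)
    L = _pathlengths_cm(montage, config, channel_ids, wavelengths)
    conc = np.stack([hbo, hbr], axis=-1)       # (n, nch, 2)
    od = conc @ E.T                             # (n, nch, 2λ)
    return od * L[None, :, :]


def mbll_invert(
    od: ODSeries, montage: Montage, config: PipelineConfig | None = None,
    wavelengths=(760.0, 850.0),
) -> ConcSeries:
    """Invert the modified Beer-Lambert law to ΔHbO/ΔHbR (µM).

    Solves the per-channel 2x2 system using the configured extinction table
    (cm^-1/µM), channel distance (cm) and partial pathlength factors.
    """
    config = config or PipelineConfig()
    E = _extinction_matrix(config, wavelengths)
    Einv = np.linalg.inv(E)
    L = _pathlengths_cm(montage, config, od.channel_ids, wavelengths)
    od_per_path = od.od / L[None, :, :]
    conc = od_per_path @ Einv.T                 # (n, nch, 2) -> hbo, hbr
    return ConcSeries(
        data={"hbo": conc[..., 0], "hbr": conc[..., 1]},
        rate=od.rate,
        channel_ids=od.channel_ids,
    )


def bandpass(
    x: np.ndarray, rate: float, low: float = 0.01, high: float = 0.08,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward with
    reflected padding); the mean is removed first so DC cannot leak.

    A band this narrow relative to the sampling rate rings for ~1/low
    seconds from any edge discontinuity, so large out-of-band components
    (cardiac, respiration, slow drift) would leak into the passband through
    the reflection edges. Three guards run first, all linear and identical
    across channels: a least-squares polynomial detrend (slow drift), a
    gentle low-pass at 4x the upper band edge (fast physiology), and a
    short cosine edge taper (residual low-pass edge transients).
    """
    if rate <= 2 * high:
        raise ValueError("sampling rate must exceed twice the upper corner")
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    x = x - x.mean(axis=0, keepdims=True)
    # polynomial drift removal (least-squares Legendre projection; a
    # projection has no impulse response, so large slow drifts cannot ring
    # through the narrow band below); order scales with duration x low
    # corner so it tracks fluctuations up to ~low/2 Hz
    p_order = min(30, max(2, int(np.ceil(2.0 * n / rate * low))))
    grid = np.linspace(-1.0, 1.0, n)
    basis = np.polynomial.legendre.legvander(grid, p_order)
    coef, *_ = np.linalg.lstsq(basis, x.reshape(n, -1), rcond=None)
    x = x - (basis @ coef).reshape(x.shape)
    pre_corner = 4.0 * high
    if pre_corner < rate / 2.0:
        # gentle low-pass (short settling) so fast components cannot kink
        # the reflection edges of the narrow band-pass
        lp = signal.butter(5, pre_corner, btype="low", fs=rate, output="sos")
        x = signal.sosfiltfilt(lp, x, axis=0, padtype="odd")
        # cosine-taper the outermost samples: residual low-pass edge
        # transients would otherwise ring for ~1/low seconds
        n_taper = min(int(round(10.0 * rate)), n // 20)
        if n_taper > 1:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_taper) / n_taper))
            shape = (n_taper,) + (1,) * (x.ndim - 1)
            x = x.copy()
            x[:n_taper] *= ramp.reshape(shape)
            x[-n_taper:] *= ramp[::-1].reshape(shape)
    sos = signal.butter(order, [low, high], btype="band", fs=rate, output="sos")
    out = signal.sosfiltfilt(sos, x, axis=0, padtype="odd")
    return out[:, 0] if squeeze else out


def total_hb(conc: ConcSeries) -> ConcSeries:
    """Add the elementwise HbT = HbO + HbR species."""
    hbo, hbr = conc.data["hbo"], conc.data["hbr"]
    if hbo.shape != hbr.shape:
        raise ValueError("HbO and HbR series are not aligned")
    data = dict(conc.data)
    data["hbt"] = hbo + hbr
    return ConcSeries(data=data, rate=conc.rate, channel_ids=conc.channel_ids,
                      boundaries=conc.boundaries)


def normalize_segment(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each channel of a segment to mean 0, SD 1 (ddof=1).

    Returns (normalized, valid) where channels with zero variance come back
    as zeros and are flagged invalid instead of propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=1, keepdims=True)
    valid = (sd > 0).ravel()
    safe_sd = np.where(sd > 0, sd, 1.0)
    out = (x - mean) / safe_sd
    out[:, ~valid] = 0.0
    return out, valid


def concat_resample(
    segments: list[np.ndarray], native_rate: float, target_rate: float = 4.0
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Concatenate normalized segments and polyphase-resample to the target
    rate. Returns the resampled series and the remapped segment-start
    indices."""
    if not segments:
        raise ValueError("no segments to concatenate")
    frac = Fraction(target_rate / native_rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    concat = np.concatenate(segments, axis=0)
    out = signal.resample_poly(concat, up, down, axis=0)
    starts = np.cumsum([0] + [len(s) for s in segments[:-1]])
    boundaries = tuple(int(round(s * up / down)) for s in starts)
    return out, boundaries


@dataclass
class SubjectResult:
    """Output of the per-subject pipeline."""

    meta: object
    conc: ConcSeries | None
    valid_channels: np.ndarray
    report: "qc.ExclusionReport"
    segments: "qc.SegmentSet | None"
    timeline: "qc.QualityTimeline | None"
    provenance: list[dict] = field(default_factory=list)


#: Stage order of the per-subject pipeline (also the provenance contract).
PIPELINE_STAGES = (
    "optical_density",
    "cardiac_screening",
    "sci_psp_segmentation",
    "wavelet_despike",
    "mbll_inversion",
    "bandpass",
    "total_hb",
    "normalize",
    "concatenate",
    "resample",
)


def run_subject_pipeline(
    rec: RawRecording,
    montage: Montage,
    config: PipelineConfig | None = None,
) -> SubjectResult:
    """Run the full screening/segmentation/preprocessing chain for one
    recording. Exclusion is a clean terminal state, never an exception."""
    config = config or PipelineConfig()
    prov: list[dict] = []

    def log_stage(stage, **params):
        prov.append({"stage": stage, **params})

    n_ch = rec.n_channels
    od = od_from_intensity(rec)
    log_stage("optical_density", n_samples=rec.n_samples, rate=rec.sampling_rate)

    retained = qc.screen_channels(od.od, rec.sampling_rate, config)
    log_stage("cardiac_screening", retained=sorted(
        rec.channel_ids[i] for i in np.flatnonzero(retained)))

    if not retained.any():
        report = qc.ExclusionReport(rec.meta.subject_id, "exclude",
                                    "no_cardiac_channels", 0.0)
        return SubjectResult(rec.meta, None, retained, report, None, None, prov)

    timeline = qc.windowed_sci_psp(od.od, rec.sampling_rate, retained, config)
    mask = qc.build_sample_mask(timeline, rec.n_samples, rec.sampling_rate, config)
    segments = qc.extract_segments(
        mask, rec.sampling_rate, config.min_segment, config.gap_tolerance
    )
    log_stage("sci_psp_segmentation", n_windows=len(timeline.window_starts),
              n_segments=len(segments.intervals),
              total_seconds=segments.total_seconds)

    report = qc.apply_exclusion(rec.meta.subject_id, rec.duration,
                                retained, segments, config)
    if report.decision == "exclude":
        return SubjectResult(rec.meta, None, retained, report, segments,
                             timeline, prov)

    scaled = scale_channel_distances(montage, rec.meta.head_circumference_mm)

    low, high = config.band
    species_segments: dict[str, list[np.ndarray]] = {s: [] for s in SPECIES}
    valid = retained.copy()
    for (i0, i1) in segments.intervals:
        seg_od = od.od[i0:i1]
        seg_len_s = (i1 - i0) / rec.sampling_rate
        if seg_len_s < 1.0 / low:
            log.info(
                "segment of %.1f s cannot resolve the %.2f Hz high-pass corner",
                seg_len_s, low,
            )
        despiked = np.empty_like(seg_od)
        for wi in range(2):
            despiked[:, :, wi] = wavelet_motion_correct(
                seg_od[:, :, wi], rec.sampling_rate, config)
        conc = mbll_invert(
            ODSeries(despiked, rec.sampling_rate, rec.channel_ids), scaled, config,
            wavelengths=rec.wavelengths,
        )
        hbo = bandpass(conc.data["hbo"], rec.sampling_rate, low, high)
        hbr = bandpass(conc.data["hbr"], rec.sampling_rate, low, high)
        hbt = hbo + hbr
        for name, arr in (("hbo", hbo), ("hbr", hbr), ("hbt", hbt)):
            normed, seg_valid = normalize_segment(arr)
            valid &= seg_valid
            species_segments[name].append(normed)
    log_stage("wavelet_despike", wavelet=config.wavelet, iqr=config.wavelet_iqr)
    log_stage("mbll_inversion", ppf=dict(config.ppf))
    log_stage("bandpass", band=list(config.band))
    log_stage("total_hb")
    log_stage("normalize", per_segment=True)

    data = {}
    boundaries: tuple[int, ...] = (0,)
    for name in SPECIES:
        data[name], boundaries = concat_resample(
            species_segments[name], rec.sampling_rate, config.target_rate
        )
    log_stage("concatenate", boundaries=list(boundaries))
    log_stage("resample", target_rate=config.target_rate,
              n_samples=data["hbt"].shape[0])

    conc_out = ConcSeries(
        data=data, rate=config.target_rate, channel_ids=rec.channel_ids,
        boundaries=boundaries,
    )
    return SubjectResult(rec.meta, conc_out, valid, report, segments,
                         timeline, prov)
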