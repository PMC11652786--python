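"""Synthetic neonatal fNIRS cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: band-limited (0.01-0.08 Hz) hemodynamic fluctuations with a
prescribed cross-channel correlation matrix, anticorrelated HbR, cardiac
pulsation with a drifting rate, respiration, Mayer waves, slow drift, white
noise, prolonged motion epochs and brief spikes, channels without cardiac
signal, and covariate effects of postnatal/gestational age on
interhemispheric connectivity. Every recording ships with its ground truth
so each downstream stage has an oracle.

Two fidelity tiers are exposed:

* :func:`simulate_recording` — full optical simulation (forward modified
  Beer-Lambert to two-wavelength intensities); exercises the whole pipeline.
* :func:`simulate_latent` — the correlated hemodynamic latent series alone,
  at an arbitrary rate; used for large statistical recovery experiments
  where optics and QC are not under test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .config import PipelineConfig
from .io import RawRecording, WAVELENGTHS
from .montage import Montage, SubjectMeta, build_default_montage, scale_channel_distances
from .preprocess import bandpass, mbll_forward

log = logging.getLogger(__name__)


@dataclass
class SimParams:
    """Generator parameters (defaults are the study conditions).

    Cohort demographics follow the reference cohort: GA ~ N(39.08, 1.31) wk
    truncated to [36.0, 42.2], PNA ~ N(22.93, 11.20) h truncated at ≥ 4,
    head circumference ~ N(347, 17) mm in [310, 380]. Connectivity baselines
    (left 0.5 > right 0.4 > inter 0.25) mirror the left-dominant structure
    the analysis is meant to detect; amplitude units are µM for hemoglobin
    and optical-density units for nuisance components.
    """

    n_subjects: int = 41
    duration_range: tuple[float, float] = (380.0, 900.0)
    sampling_rate: float = 10.17
    # hemodynamics
    hemo_amp: float = 3.0              # µM, HbO fluctuation scale
    hbr_coupling: float = -0.3
    hbr_noise: float = 0.2             # independent band-limited HbR noise (×hemo_amp)
    band: tuple[float, float] = (0.01, 0.08)
    # physiology (OD units)
    cardiac_amp: float = 0.008
    cardiac_bpm: tuple[float, float] = (70.0, 200.0)
    resp_band: tuple[float, float] = (0.6, 1.2)
    resp_amp: float = 0.0005
    mayer_freq: float = 0.1
    mayer_amp: float = 0.0003
    drift_amp: float = 0.005
    noise_sd: float = 0.002
    # motion
    motion_epoch_rate: float = 0.5     # epochs per minute
    epoch_duration: tuple[float, float] = (2.0, 15.0)
    motion_noise_factor: float = 30.0
    motion_cardiac_factor: float = 0.05
    spike_rate: float = 1.0            # spikes per minute
    spike_duration: tuple[float, float] = (0.2, 1.5)
    spike_amp: float = 0.02
    dead_channel_prob: float = 0.05
    # connectivity structure
    r_left: float = 0.5
    r_right: float = 0.4
    r_inter: float = 0.25
    beta_pna_inter: float = 0.004      # z units per hour
    beta_ga_inter: float = 0.0         # z units per week
    subject_re_sd: float = 0.05        # z units, shared per-subject offset
    sex_re_sd: float = 0.02            # z units, shared per-sex offset
    conn_noise_sd: float = 0.05        # z units, per-pair jitter
    exact_correlation: bool = True
    # demographics
    ga_mean: float = 39.08
    ga_sd: float = 1.31
    ga_range: tuple[float, float] = (36.0, 42.2)
    pna_mean: float = 22.93
    pna_sd: float = 11.20
    pna_min: float = 4.0
    hc_mean: float = 347.0
    hc_sd: float = 17.0
    hc_range: tuple[float, float] = (310.0, 380.0)
    baseline: float = 1.0

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2.0
        for lo, hi in (self.band, self.resp_band):
            if not (0 < lo < hi < nyq):
                raise ValueError("band edges must lie within (0, Nyquist)")
        if not (0 < self.cardiac_bpm[0] < self.cardiac_bpm[1] < 60 * nyq):
            raise ValueError("cardiac band must lie within (0, Nyquist)")
        for r in (self.r_left, self.r_right, self.r_inter):
            if not -1 < r < 1:
                raise ValueError("baseline correlations must lie in (-1, 1)")


@dataclass
class GroundTruth:
    """Per-subject generator truth used as the downstream oracle."""

    true_correlation: np.ndarray               # (20, 20), PSD, unit diagonal
    beta_pna_inter: float
    beta_ga: float
    motion_schedule: list[tuple[float, float, str]]  # (start s, end s, kind)
    dead_channels: set[int] = field(default_factory=set)
    cardiac_rate_track: np.ndarray = field(default_factory=lambda: np.array([]))
    duration: float = 0.0


# --------------------------------------------------------------------------
# cohort sampling
# --------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo=-np.inf, hi=np.inf, size=None):
    """Rejection-sampled truncated normal."""
    shape = () if size is None else (size,)
    out = np.empty(shape if shape else (1,))
    n = out.size
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 8))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out.flat[filled:filled + take] = keep[:take]
        filled += take
    return float(out[0]) if size is None else out


def sample_cohort(params: SimParams, seed: int) -> list[SubjectMeta]:
    """Draw a reproducible cohort of subject demographics."""
    if params.n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    metas = []
    for i in range(params.n_subjects):
        ga = _truncated_normal(rng, params.ga_mean, params.ga_sd, *params.ga_range)
        pna = _truncated_normal(rng, params.pna_mean, params.pna_sd, params.pna_min)
        hc = _truncated_normal(rng, params.hc_mean, params.hc_sd, *params.hc_range)
        sex = "female" if rng.random() < 0.5 else "male"
        metas.append(SubjectMeta(
            subject_id=f"sim{i:03d}",
            gestational_age_wk=round(ga, 2),
            postnatal_age_h=round(pna, 2),
            sex=sex,
            head_circumference_mm=round(hc, 0),
        ))
    return metas


# --------------------------------------------------------------------------
# true correlation structure
# --------------------------------------------------------------------------

def _hemisphere_blocks(montage: Montage):
    left = np.array([c.hemisphere == "left" for c in montage.channels])
    return left, ~left


def nearest_psd_correlation(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive semi-definite
    matrix with unit diagonal (eigenvalue clipping + diagonal rescale)."""
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() >= eps:
        out = R.copy()
    else:
        out = (V * np.maximum(w, eps)) @ V.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def make_true_correlation(
    meta: SubjectMeta,
    params: SimParams,
    montage: Montage | None = None,
) -> np.ndarray:
    """Deterministic block correlation matrix for one subject.

    Intrahemispheric blocks sit at the left/right baselines; the
    interhemispheric block is tanh(atanh(r_inter) + β_PNA·(PNA − mean PNA)
    + β_GA·(GA − mean GA)), so covariate effects are linear in Fisher-z
    units and the matrix stays inside (−1, 1).
    """
    montage = montage or build_default_montage()
    left, right = _hemisphere_blocks(montage)
    z_inter = np.arctanh(params.r_inter)
    if params.beta_pna_inter and meta.postnatal_age_h is not None:
        z_inter += params.beta_pna_inter * (meta.postnatal_age_h - params.pna_mean)
    if params.beta_ga_inter and meta.gestational_age_wk is not None:
        z_inter += params.beta_ga_inter * (meta.gestational_age_wk - params.ga_mean)
    r_inter = np.tanh(z_inter)
    n = montage.n_channels
    R = np.empty((n, n))
    R[np.ix_(left, left)] = params.r_left
    R[np.ix_(right, right)] = params.r_right
    R[np.ix_(left, right)] = r_inter
    R[np.ix_(right, left)] = r_inter
    np.fill_diagonal(R, 1.0)
    return nearest_psd_correlation(R)


def make_cohort_truths(
    metas: list[SubjectMeta],
    params: SimParams,
    seed: int,
    montage: Montage | None = None,
) -> list[GroundTruth]:
    """Ground truths for a cohort, adding between-subject connectivity
    heterogeneity in Fisher-z space: a per-subject offset, a per-sex offset,
    and symmetric per-pair jitter, all on the off-diagonal."""
    montage = montage or build_default_montage()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    u_sex = {s: rng.normal(0.0, params.sex_re_sd) for s in ("female", "male")}
    n = montage.n_channels
    truths = []
    for meta in metas:
        R = make_true_correlation(meta, params, montage)
        z = np.arctanh(np.clip(R, -1 + 1e-12, 1 - 1e-12))
        u_s = rng.normal(0.0, params.subject_re_sd)
        eps = rng.normal(0.0, params.conn_noise_sd, size=(n, n))
        eps = (eps + eps.T) / np.sqrt(2.0)
        off = ~np.eye(n, dtype=bool)
        z[off] += u_s + u_sex.get(meta.sex, 0.0) + eps[off]
        R_j = np.tanh(z)
        np.fill_diagonal(R_j, 1.0)
        truths.append(GroundTruth(
            true_correlation=nearest_psd_correlation(R_j),
            beta_pna_inter=params.beta_pna_inter,
            beta_ga=params.beta_ga_inter,
            motion_schedule=[],
            dead_channels=set(),
            duration=0.0,
        ))
    return truths


# --------------------------------------------------------------------------
# signal synthesis
# --------------------------------------------------------------------------

def simulate_latent(
    R: np.ndarray,
    n_samples: int,
    rate: float,
    rng: np.random.Generator,
    band: tuple[float, float] = (0.01, 0.08),
    exact: bool = True,
) -> np.ndarray:
    """Band-limited multichannel series with target correlation R.

    The series is synthesized in the frequency domain on a brick-wall
    support just inside ``band`` (random Gaussian Fourier coefficients), so
    all of its energy lies where the analysis band-pass is close to flat.

    With ``exact`` the columns are whitened against the covariance of their
    *band-pass filtered* version (the same zero-phase Butterworth the
    preprocessing applies), so the sample correlation of the band-passed
    latent equals R to numerical precision — downstream correlation
    estimates then deviate from truth only through despiking/resampling, not
    through spectral sampling noise. The latent's own sample correlation is
    within the filter's in-band gain spread of R. Without ``exact`` the
    correlation holds in expectation only, with genuine sampling
    variability (used for null-calibration experiments).
    """
    n_ch = R.shape[0]
    lo, hi = band
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    support = (freqs >= 1.2 * lo) & (freqs <= 0.94 * hi)
    n_modes = int(support.sum())
    if n_modes < 2:
        raise ValueError("series too short for the hemodynamic band")
    coeff = np.zeros((freqs.size, n_ch), dtype=complex)
    coeff[support] = (
        rng.standard_normal((n_modes, n_ch))
        + 1j * rng.standard_normal((n_modes, n_ch))
    )
    X = np.fft.irfft(coeff, n=n_samples, axis=0)
    X /= X.std(axis=0, ddof=0)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(n_ch))
    if exact and n_modes < n_ch + 2:
        log.info(
            "only %d spectral modes in band for %d channels; falling back "
            "to in-expectation correlation imposition", n_modes, n_ch,
        )
        exact = False
    if exact:
        Z = bandpass(X, rate, lo, hi)
        covZ = (Z.T @ Z) / n_samples
        W = np.linalg.cholesky(covZ)
        Xw = np.linalg.solve(W, X.T).T   # band-passed Xw has identity cov
        Y = Xw @ L.T
    else:
        Y = X @ L.T
    return Y


def _poisson_schedule(rng, duration, rate_per_min, dur_range):
    n = rng.poisson(rate_per_min * duration / 60.0)
    events = []
    for _ in range(n):
        d = rng.uniform(*dur_range)
        start = rng.uniform(0.0, max(duration - d, 0.0))
        events.append((float(start), float(start + d)))
    return sorted(events)


def plan_ground_truth(
    meta: SubjectMeta,
    params: SimParams,
    seed: int,
    duration: float | None = None,
    montage: Montage | None = None,
    base_truth: GroundTruth | None = None,
) -> GroundTruth:
    """Complete a subject's ground truth with duration, motion schedule,
    dead channels and cardiac-rate track."""
    montage = montage or build_default_montage()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    if duration is None:
        duration = float(rng.uniform(*params.duration_range))
    if duration < 150.0:
        raise ValueError("duration must be at least 150 s for the analysis band")
    R = (base_truth.true_correlation if base_truth is not None
         else make_true_correlation(meta, params, montage))
    n = int(round(duration * params.sampling_rate))
    # smoothly drifting cardiac rate inside the physiological band
    lo, hi = params.cardiac_bpm
    base = rng.uniform(lo + 10, hi - 30)
    walk = np.cumsum(rng.standard_normal(n)) * 0.02
    walk = signal.sosfiltfilt(
        signal.butter(2, 0.02, fs=params.sampling_rate, output="sos"), walk
    )
    track = np.clip(base + walk, lo, hi)
    epochs = [(s, e, "epoch") for s, e in _poisson_schedule(
        rng, duration, params.motion_epoch_rate, params.epoch_duration)]
    spikes = [(s, e, "spike") for s, e in _poisson_schedule(
        rng, duration, params.spike_rate, params.spike_duration)]
    dead = {int(c.id) for c in montage.channels
            if rng.random() < params.dead_channel_prob}
    if len(dead) >= montage.n_channels:
        dead.pop()
    return GroundTruth(
        true_correlation=R,
        beta_pna_inter=params.beta_pna_inter,
        beta_ga=params.beta_ga_inter,
        motion_schedule=sorted(epochs + spikes),
        dead_channels=dead,
        cardiac_rate_track=track,
        duration=duration,
    )


def simulate_recording(
    meta: SubjectMeta,
    truth: GroundTruth,
    params: SimParams,
    seed: int,
    montage: Montage | None = None,
    config: PipelineConfig | None = None,
) -> RawRecording:
    """Full optical simulation of one recording.

    The correlated hemodynamic latent drives ΔHbO (µM); ΔHbR is negatively
    coupled plus small independent band-limited noise. Concentrations map to
    ΔOD through the same forward modified Beer-Lambert model (extinction
    table, PPF, head-scaled distances) the preprocessing inverts; cardiac,
    respiration, Mayer-wave, drift, white-noise, motion-epoch and spike
    components are added in OD; intensity = baseline · exp(−ΔOD).
    """
    montage = montage or build_default_montage()
    config = config or PipelineConfig()
    fs = params.sampling_rate
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    n = int(round(truth.duration * fs))
    n_ch = montage.n_channels
    t = np.arange(n) / fs

    latent = simulate_latent(truth.true_correlation, n, fs, rng, params.band,
                             exact=params.exact_correlation)
    hbo = params.hemo_amp * latent
    hbr_extra = bandpass(rng.standard_normal((n, n_ch)), fs, *params.band)
    sd = hbr_extra.std(axis=0, ddof=0)
    hbr_extra /= np.where(sd > 0, sd, 1.0)
    hbr = params.hbr_coupling * hbo + params.hbr_noise * params.hemo_amp * hbr_extra

    scaled = scale_channel_distances(montage, meta.head_circumference_mm)
    od = mbll_forward(hbo, hbr, scaled, config,
                      channel_ids=montage.channel_ids, wavelengths=WAVELENGTHS)

    # envelopes for motion epochs
    noise_env = np.ones(n)
    cardiac_env = np.ones(n)
    for (s, e, kind) in truth.motion_schedule:
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        if kind == "epoch":
            noise_env[i0:i1] = params.motion_noise_factor
            cardiac_env[i0:i1] = params.motion_cardiac_factor

    # cardiac: shared phase, per-channel amplitude, absent on dead channels
    phase = 2 * np.pi * np.cumsum(truth.cardiac_rate_track / 60.0) / fs
    card_wave = np.sin(phase) + 0.3 * np.sin(2 * phase + 0.5)
    ch_amp = params.cardiac_amp * rng.uniform(0.7, 1.3, size=n_ch)
    for k, cid in enumerate(montage.channel_ids):
        if cid in truth.dead_channels:
            ch_amp[k] = 0.0
    wl_gain = np.array([1.0, 1.2])
    cardiac = (cardiac_env * card_wave)[:, None, None] \
        * ch_amp[None, :, None] * wl_gain[None, None, :]

    resp_f = rng.uniform(*params.resp_band)
    resp = params.resp_amp * np.sin(2 * np.pi * resp_f * t + rng.uniform(0, 2 * np.pi))
    mayer = params.mayer_amp * np.sin(
        2 * np.pi * params.mayer_freq * t + rng.uniform(0, 2 * np.pi))
    shared = (resp + mayer)[:, None, None] * rng.uniform(0.5, 1.5, (1, n_ch, 2))

    # slow drift synthesized strictly below the analysis band (< 0.005 Hz)
    fr = np.fft.rfftfreq(n, 1.0 / fs)
    drift_support = (fr > 0) & (fr < 0.005)
    dcoef = np.zeros((fr.size, n_ch, 2), dtype=complex)
    if drift_support.any():
        nd = int(drift_support.sum())
        dcoef[drift_support] = (rng.standard_normal((nd, n_ch, 2))
                                + 1j * rng.standard_normal((nd, n_ch, 2)))
    drift = np.fft.irfft(dcoef, n=n, axis=0)
    sd_d = drift.std(axis=0, keepdims=True)
    drift = params.drift_amp * drift / np.where(sd_d > 0, sd_d, 1.0)

    noise = params.noise_sd * rng.standard_normal((n, n_ch, 2)) \
        * noise_env[:, None, None]

    spikes = np.zeros((n, n_ch, 2))
    for (s, e, kind) in truth.motion_schedule:
        if kind != "spike":
            continue
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        if i1 <= i0:
            continue
        tau = max((i1 - i0) / 3.0, 1.0)
        pulse = np.exp(-np.arange(i1 - i0) / tau)
        amp = params.spike_amp * rng.choice([-1.0, 1.0], size=(n_ch, 2)) \
            * rng.uniform(0.5, 1.5, size=(n_ch, 2))
        spikes[i0:i1] += pulse[:, None, None] * amp[None, :, :]

    od_total = od + cardiac + shared + drift + noise + spikes
    intensity = params.baseline * np.exp(-od_total)
    return RawRecording(
        meta=meta, intensity=intensity, sampling_rate=fs,
        channel_ids=montage.channel_ids,
    )


def simulate_cohort(
    params: SimParams, seed: int,
    montage: Montage | None = None,
    config: PipelineConfig | None = None,
):
    """Yield (RawRecording, GroundTruth) for a full cohort, reproducibly."""
    montage = montage or build_default_montage()
    metas = sample_cohort(params, seed)
    truths = make_cohort_truths(metas, params, seed, montage)
    ss = np.random.SeedSequence([seed, 505]).spawn(len(metas))
    for meta, base, sub_ss in zip(metas, truths, ss):
        sub_seed = int(sub_ss.generate_state(1)[0] % (2**31 - 1))
        truth = plan_ground_truth(meta, params, sub_seed, montage=montage,
                                  base_truth=base)
        rec = simulate_recording(meta, truth, params, sub_seed, montage, config)
        yield rec, truth


# --------------------------------------------------------------------------
# truth persistence
# --------------------------------------------------------------------------

_TRUTH_KEYS = {"true_correlation", "beta_pna_inter", "beta_ga",
               "motion_schedule", "dead_channels", "cardiac_rate_track",
               "duration"}


def export_truth(truth: GroundTruth, path: str | Path) -> None:
    d = {
        "true_correlation": truth.true_correlation.tolist(),
        "beta_pna_inter": truth.beta_pna_inter,
        "beta_ga": truth.beta_ga,
        "motion_schedule": [list(ev) for ev in truth.motion_schedule],
        "dead_channels": sorted(truth.dead_channels),
        "cardiac_rate_track": np.asarray(truth.cardiac_rate_track).tolist(),
        "duration": truth.duration,
    }
    Path(path).write_text(json.dumps(d))


def load_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    missing = _TRUTH_KEYS - set(d)
    if missing:
        raise ValueError(f"truth file missing fields: {sorted(missing)}")
    return GroundTruth(
        true_correlation=np.array(d["true_correlation"]),
        beta_pna_inter=float(d["beta_pna_inter"]),
        beta_ga=float(d["beta_ga"]),
        motion_schedule=[(float(s), float(e), str(k))
                         for s, e, k in d["motion_schedule"]],
        dead_channels=set(int(c) for c in d["dead_channels"]),
        cardiac_rate_track=np.array(d["cardiac_rate_track"]),
        duration=float(d["duration"]),
    )
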