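"""Pipeline configuration shared by every processing stage.

All fixed parameters of the quality-control, preprocessing and inference
stages live in a single flat :class:`PipelineConfig` so that a run can be
reproduced from its config snapshot alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Molar extinction coefficients in cm^-1 per µM (standard compilation
#: values for oxy-/deoxyhemoglobin at the two instrument wavelengths).
DEFAULT_EXTINCTION: dict[float, dict[str, float]] = {
    760.0: {"hbo": 586.0e-6, "hbr": 1548.52e-6},
    850.0: {"hbo": 1058.0e-6, "hbr": 691.32e-6},
}

#: Age-appropriate partial pathlength factors (dimensionless multipliers of
#: the geometric source-detector distance in the modified Beer-Lambert law).
DEFAULT_PPF: dict[float, float] = {760.0: 0.1063, 850.0: 0.0845}


@dataclass
class PipelineConfig:
    """Fixed parameters of the full analysis chain.

    Units: window/segment quantities in seconds, bands in the units given by
    the field name (bpm for the cardiac band, Hz for the hemodynamic band),
    thresholds dimensionless.
    """

    # --- quality control -------------------------------------------------
    sci_threshold: float = 0.1
    psp_threshold: float = 0.03
    window_length: float = 5.0
    window_overlap: float = 4.0
    cardiac_band_bpm: tuple[float, float] = (60.0, 210.0)
    cardiac_peak_ratio: float = 3.0       # spectral peak-ratio for channel screening
    channel_fraction: float = 0.75        # fraction of retained channels per good window
    min_segment: float = 50.0
    gap_tolerance: float = 2.0
    min_total: float = 150.0              # 2.5 min survival floor
    # --- preprocessing ---------------------------------------------------
    wavelet: str = "db2"
    wavelet_sd: float = 0.8               # SD-threshold convention
    wavelet_iqr: float = 0.6              # equivalent IQR convention (normative here)
    ppf: dict[float, float] = field(default_factory=lambda: dict(DEFAULT_PPF))
    band: tuple[float, float] = (0.01, 0.08)
    target_rate: float = 4.0
    extinction: dict[float, dict[str, float]] = field(
        default_factory=lambda: {w: dict(e) for w, e in DEFAULT_EXTINCTION.items()}
    )
    # --- inference -------------------------------------------------------
    fdr_q: float = 0.05
    n_model_bonferroni: int = 3
    min_pair_datapoints: int = 10
    min_channel_fraction: float = 0.5     # subject inclusion floor for hemispheric models
    sex_as_fixed: bool = False            # sensitivity switch for the LME
    reml: bool = True
    center_covariates: bool = False
    # --- misc ------------------------------------------------------------
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.window_overlap >= self.window_length:
            raise ValueError("window_overlap must be shorter than window_length")
        low, high = self.band
        if not (0.0 < low < high):
            raise ValueError("band must satisfy 0 < low < high")
        if high >= self.target_rate / 2.0:
            raise ValueError("band high corner must lie below the target-rate Nyquist")
        for name in ("sci_threshold", "psp_threshold", "min_segment",
                     "gap_tolerance", "min_total", "wavelet_sd", "wavelet_iqr",
                     "target_rate", "cardiac_peak_ratio"):
            if getattr(self, name) is None:
                raise ValueError(f"{name} must be set")
        lo_bpm, hi_bpm = self.cardiac_band_bpm
        if not (0.0 < lo_bpm < hi_bpm):
            raise ValueError("cardiac band must satisfy 0 < low < high")
        if not all(v > 0 for v in self.ppf.values()):
            raise ValueError("partial pathlength factors must be positive")

    @property
    def cardiac_band_hz(self) -> tuple[float, float]:
        lo, hi = self.cardiac_band_bpm
        return lo / 60.0, hi / 60.0

    # -- flat key-value persistence --------------------------------------
    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["cardiac_band_bpm"] = list(self.cardiac_band_bpm)
        d["band"] = list(self.band)
        d["ppf"] = {str(k): v for k, v in self.ppf.items()}
        d["extinction"] = {str(k): dict(v) for k, v in self.extinction.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["cardiac_band_bpm"] = tuple(d["cardiac_band_bpm"])
        d["band"] = tuple(d["band"])
        d["ppf"] = {float(k): float(v) for k, v in d["ppf"].items()}
        d["extinction"] = {
            float(k): {s: float(x) for s, x in v.items()}
            for k, v in d["extinction"].items()
        }
        return cls(**d)
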