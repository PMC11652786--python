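"""Channel montage model and pair taxonomy.

The instrument couples 8 LED sources (760/850 nm) with 8 detectors into 20
measurement channels, 10 per hemisphere, with a mean source-detector
separation of about 35.7 mm (SD 9.5 mm). Downstream analysis depends only on
each channel's hemisphere label and separation, never on 3-D optode
coordinates, so the bundled default layout records exactly those.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HEMISPHERES = ("left", "right")
PAIR_CLASSES = ("left_intra", "right_intra", "inter")

#: Head circumference (mm) the default layout distances refer to.
REFERENCE_CIRCUMFERENCE_MM = 350.0


@dataclass(frozen=True)
class Channel:
    id: int
    source_id: int
    detector_id: int
    hemisphere: str
    distance_mm: float

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere label {self.hemisphere!r}")
        if self.distance_mm <= 0:
            raise ValueError("channel distance must be positive")


@dataclass(frozen=True)
class Montage:
    channels: tuple[Channel, ...]
    reference_circumference_mm: float = REFERENCE_CIRCUMFERENCE_MM

    def __post_init__(self) -> None:
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate channel ids in montage")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(c.id for c in self.channels)

    @property
    def distances_mm(self) -> np.ndarray:
        return np.array([c.distance_mm for c in self.channels])

    @property
    def mean_distance_mm(self) -> float:
        return float(self.distances_mm.mean())

    @property
    def sd_distance_mm(self) -> float:
        return float(self.distances_mm.std(ddof=1))

    def hemisphere_of(self, channel_id: int) -> str:
        return self._by_id()[channel_id].hemisphere

    def distance_of(self, channel_id: int) -> float:
        return self._by_id()[channel_id].distance_mm

    def _by_id(self) -> dict[int, Channel]:
        return {c.id: c for c in self.channels}


@dataclass
class SubjectMeta:
    """Per-subject demographics; any field other than the id may be missing."""

    subject_id: str
    gestational_age_wk: float | None = None
    postnatal_age_h: float | None = None
    sex: str | None = None
    head_circumference_mm: float | None = None

    def __post_init__(self) -> None:
        if self.gestational_age_wk is not None and not (
            30.0 <= self.gestational_age_wk <= 45.0
        ):
            raise ValueError("gestational age out of plausible range [30, 45] weeks")
        if self.postnatal_age_h is not None and self.postnatal_age_h < 0:
            raise ValueError("postnatal age must be non-negative")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex label {self.sex!r}")


def load_default_layout() -> pd.DataFrame:
    """Bundled 10-10-inspired layout table (channel, source, detector,
    hemisphere, distance_mm)."""
    with resources.files("nirsfc.data").joinpath("default_layout.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_cohort() -> pd.DataFrame:
    """Demographics and scan-duration table for the neonatal reference cohort
    (41 infants; printed per-subject gestational/postnatal age, sex, head
    size, and total/post-segmentation scan durations)."""
    with resources.files("nirsfc.data").joinpath("reference_cohort.csv").open() as fh:
        return pd.read_csv(fh)


def build_default_montage(
    layout: pd.DataFrame | None = None,
    reference_circumference_mm: float = REFERENCE_CIRCUMFERENCE_MM,
) -> Montage:
    """Build a Montage from a layout table.

    The layout must have 20 rows with unique channel ids and exactly 10
    channels per hemisphere.
    """
    if layout is None:
        layout = load_default_layout()
    if len(layout) != 20:
        raise ValueError(f"expected 20 channels, layout has {len(layout)}")
    channels = tuple(
        Channel(
            id=int(r.channel),
            source_id=int(r.source),
            detector_id=int(r.detector),
            hemisphere=str(r.hemisphere),
            distance_mm=float(r.distance_mm),
        )
        for r in layout.itertuples()
    )
    montage = Montage(channels, reference_circumference_mm)
    counts = {h: sum(c.hemisphere == h for c in channels) for h in HEMISPHERES}
    if counts != {"left": 10, "right": 10}:
        raise ValueError(f"expected 10 channels per hemisphere, got {counts}")
    return montage


def enumerate_pairs(montage: Montage) -> list[tuple[int, int]]:
    """All unordered channel pairs (i < j), in ascending id order."""
    ids = sorted(montage.channel_ids)
    return [(ids[a], ids[b]) for a in range(len(ids)) for b in range(a + 1, len(ids))]


def classify_pair(montage: Montage, pair: tuple[int, int]) -> str:
    """Classify a channel pair as left_intra, right_intra, or inter."""
    by_id = montage._by_id()
    for cid in pair:
        if cid not in by_id:
            raise KeyError(f"unknown channel id {cid}")
    h1, h2 = (by_id[c].hemisphere for c in pair)
    if h1 == h2:
        return f"{h1}_intra"
    return "inter"


def scale_channel_distances(
    montage: Montage, head_circumference_mm: float | None
) -> Montage:
    """Scale every channel distance by head circumference relative to the
    reference circumference the layout was drawn for.

    A missing circumference returns the montage unscaled with a logged
    warning rather than excluding the subject.
    """
    if head_circumference_mm is None:
        log.warning(
            "head circumference missing; using unscaled reference distances"
        )
        return montage
    if head_circumference_mm <= 0:
        raise ValueError("head circumference must be positive")
    ratio = head_circumference_mm / montage.reference_circumference_mm
    channels = tuple(
        replace(c, distance_mm=c.distance_mm * ratio) for c in montage.channels
    )
    return Montage(channels, montage.reference_circumference_mm)


def gestational_age_decimal(weeks: int, days: int) -> float:
    """Convert a weeks+days gestational age to decimal weeks, rounded half
    away from zero to 2 decimals (38 weeks + 5 days -> 38.71)."""
    if not 0 <= days <= 6:
        raise ValueError("days must be in 0..6")
    ga = Decimal(weeks) + Decimal(days) / Decimal(7)
    return float(ga.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def meta_from_row(row: pd.Series | dict) -> SubjectMeta:
    """Build a SubjectMeta from one row of a cohort table, treating NaN as
    missing."""
    def get(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    ga = get("gestational_age_wk")
    pna = get("postnatal_age_h")
    hc = get("head_circumference_mm")
    return SubjectMeta(
        subject_id=str(row["subject_id"]),
        gestational_age_wk=None if ga is None else float(ga),
        postnatal_age_h=None if pna is None else float(pna),
        sex=get("sex"),
        head_circumference_mm=None if hc is None else float(hc),
    )
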