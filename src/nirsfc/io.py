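"""Recording container and I/O (SNIRF and a plain tabular dialect).

A recording holds two-wavelength continuous-wave intensity series for the 20
montage channels. Two on-disk forms are supported:

* SNIRF (HDF5) — the field's exchange format; a minimal continuous-wave
  subset is written (dataTimeSeries + measurementList + probe + metaDataTags)
  that standard readers such as MNE can open.
* tabular CSV — one wide UTF-8 table per recording with a header row and
  columns ``time_s, ch<k>_760, ch<k>_850``; convenient for inspectable
  fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import SubjectMeta

WAVELENGTHS = (760.0, 850.0)


@dataclass
class RawRecording:
    """Two-wavelength intensity series plus subject metadata.

    ``intensity`` has shape (n_samples, n_channels, 2) with the wavelength
    axis ordered like :data:`WAVELENGTHS`.
    """

    meta: SubjectMeta
    intensity: np.ndarray
    sampling_rate: float = 10.17
    wavelengths: tuple[float, float] = WAVELENGTHS
    channel_ids: tuple[int, ...] = tuple(range(1, 21))

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise ValueError(
                "intensity must have shape (n_samples, n_channels, 2); "
                f"got {self.intensity.shape}"
            )
        if self.intensity.shape[1] != len(self.channel_ids):
            raise ValueError("channel axis does not match channel_ids")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


# --------------------------------------------------------------------------
# tabular dialect
# --------------------------------------------------------------------------

def write_tabular(rec: RawRecording, path: str | Path) -> None:
    cols = {"time_s": np.arange(rec.n_samples) / rec.sampling_rate}
    for ci, cid in enumerate(rec.channel_ids):
        for wi, wl in enumerate(rec.wavelengths):
            cols[f"ch{cid}_{int(wl)}"] = rec.intensity[:, ci, wi]
    df = pd.DataFrame(cols)
    meta = rec.meta
    header = (
        f"# subject_id={meta.subject_id}"
        f" sampling_rate={rec.sampling_rate!r}"
        f" gestational_age_wk={meta.gestational_age_wk!r}"
        f" postnatal_age_h={meta.postnatal_age_h!r}"
        f" sex={meta.sex}"
        f" head_circumference_mm={meta.head_circumference_mm!r}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def _parse_optional(tok: str) -> float | None:
    return None if tok == "None" else float(tok)


def read_tabular(path: str | Path) -> RawRecording:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("tabular recording must start with a '# key=value' line")
        kv = dict(tok.split("=", 1) for tok in header[1:].split())
        df = pd.read_csv(fh)
    sex = kv.get("sex")
    meta = SubjectMeta(
        subject_id=kv["subject_id"],
        gestational_age_wk=_parse_optional(kv["gestational_age_wk"]),
        postnatal_age_h=_parse_optional(kv["postnatal_age_h"]),
        sex=None if sex == "None" else sex,
        head_circumference_mm=_parse_optional(kv["head_circumference_mm"]),
    )
    rate = float(kv["sampling_rate"])
    chan_ids = []
    for col in df.columns:
        if col.startswith("ch") and col.endswith("_760"):
            chan_ids.append(int(col[2:-4]))
    if not chan_ids:
        raise ValueError("no channel columns found")
    n = len(df)
    intensity = np.empty((n, len(chan_ids), 2))
    for ci, cid in enumerate(chan_ids):
        for wi, wl in enumerate(WAVELENGTHS):
            col = f"ch{cid}_{int(wl)}"
            if col not in df.columns:
                raise ValueError(f"missing wavelength column {col}")
            intensity[:, ci, wi] = df[col].to_numpy()
    return RawRecording(
        meta=meta,
        intensity=intensity,
        sampling_rate=rate,
        channel_ids=tuple(chan_ids),
    )


# --------------------------------------------------------------------------
# SNIRF (minimal continuous-wave subset)
# --------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def _write_str(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=value, dtype=_STR)


def _source_detector_map(channel_ids) -> dict[int, tuple[int, int]]:
    """Channel id -> (source, detector). Uses the bundled layout for the
    standard 20-channel montage; otherwise a one-to-one schematic mapping."""
    if tuple(channel_ids) == tuple(range(1, 21)):
        from .montage import load_default_layout

        layout = load_default_layout()
        return {int(r.channel): (int(r.source), int(r.detector))
                for r in layout.itertuples()}
    return {cid: (k + 1, k + 1) for k, cid in enumerate(channel_ids)}


def write_snirf(rec: RawRecording, path: str | Path) -> None:
    """Write a minimal continuous-wave SNIRF file."""
    meta = rec.meta
    sd_map = _source_detector_map(rec.channel_ids)
    n_src = max(max(s for s, _ in sd_map.values()),
                max(d for _, d in sd_map.values()))
    with h5py.File(path, "w") as f:
        _write_str(f, "formatVersion", "1.0")
        nirs = f.create_group("nirs")
        tags = nirs.create_group("metaDataTags")
        _write_str(tags, "SubjectID", meta.subject_id)
        _write_str(tags, "MeasurementDate", "unknown")
        _write_str(tags, "MeasurementTime", "unknown")
        _write_str(tags, "LengthUnit", "mm")
        _write_str(tags, "TimeUnit", "s")
        _write_str(tags, "FrequencyUnit", "Hz")
        for key, val in (
            ("GestationalAgeWeeks", meta.gestational_age_wk),
            ("PostnatalAgeHours", meta.postnatal_age_h),
            ("Sex", meta.sex),
            ("HeadCircumferenceMm", meta.head_circumference_mm),
        ):
            if val is not None:
                _write_str(tags, key, str(val))

        data = nirs.create_group("data1")
        n, nch, _ = rec.intensity.shape
        flat = rec.intensity.reshape(n, nch * 2)  # channel-major, wavelength inner
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset(
            "time", data=np.arange(n, dtype=float) / rec.sampling_rate
        )
        for ci, cid in enumerate(rec.channel_ids):
            src, det = sd_map[cid]
            for wi in range(2):
                ml = data.create_group(f"measurementList{ci * 2 + wi + 1}")
                ml.create_dataset("sourceIndex", data=np.int32(src))
                ml.create_dataset("detectorIndex", data=np.int32(det))
                ml.create_dataset("wavelengthIndex", data=np.int32(wi + 1))
                ml.create_dataset("dataType", data=np.int32(1))
                ml.create_dataset("dataTypeIndex", data=np.int32(1))
                ml.create_dataset("channelId", data=np.int32(cid))

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(rec.wavelengths))
        # schematic positions: left sources x<0, right x>0, spread in y
        ys = np.arange(n_src) * 20.0
        src = np.column_stack([np.where(ys < ys.mean(), -40.0, 40.0), ys, 0 * ys])
        det = np.column_stack([np.where(ys < ys.mean(), -60.0, 60.0), ys, 0 * ys])
        probe.create_dataset("sourcePos3D", data=src)
        probe.create_dataset("detectorPos3D", data=det)


def _read_scalar_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        tags = nirs["metaDataTags"]

        def tag(name):
            return _read_scalar_str(tags[name]) if name in tags else None

        ga = tag("GestationalAgeWeeks")
        pna = tag("PostnatalAgeHours")
        hc = tag("HeadCircumferenceMm")
        meta = SubjectMeta(
            subject_id=tag("SubjectID") or "unknown",
            gestational_age_wk=None if ga is None else float(ga),
            postnatal_age_h=None if pna is None else float(pna),
            sex=tag("Sex"),
            head_circumference_mm=None if hc is None else float(hc),
        )
        data = nirs["data1"]
        flat = np.asarray(data["dataTimeSeries"])
        t = np.asarray(data["time"])
        if t.size < 2:
            raise ValueError("time vector too short to infer sampling rate")
        rate = float(1.0 / np.median(np.diff(t)))

        n_meas = flat.shape[1]
        wl_index = np.zeros(n_meas, dtype=int)
        chan_of_col = np.zeros(n_meas, dtype=int)
        for k in range(1, n_meas + 1):
            ml = data[f"measurementList{k}"]
            wl_index[k - 1] = int(np.asarray(ml["wavelengthIndex"]))
            if "channelId" in ml:
                chan_of_col[k - 1] = int(np.asarray(ml["channelId"]))
            else:  # fall back to source/detector pairing order
                chan_of_col[k - 1] = (k + 1) // 2
        chan_ids = sorted(set(chan_of_col))
        n = flat.shape[0]
        intensity = np.full((n, len(chan_ids), 2), np.nan)
        for col in range(n_meas):
            ci = chan_ids.index(chan_of_col[col])
            intensity[:, ci, wl_index[col] - 1] = flat[:, col]
        if np.isnan(intensity).any():
            raise ValueError("a channel is missing one of the two wavelengths")
    return RawRecording(
        meta=meta, intensity=intensity, sampling_rate=rate,
        channel_ids=tuple(chan_ids),
    )


# --------------------------------------------------------------------------
# format dispatch
# --------------------------------------------------------------------------

def write_recording(rec: RawRecording, path: str | Path, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "snirf":
        write_snirf(rec, path)
    elif fmt == "tabular":
        write_tabular(rec, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> RawRecording:
    fmt = format or _infer_format(path)
    if fmt == "snirf":
        return read_snirf(path)
    if fmt == "tabular":
        return read_tabular(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".snirf":
        return "snirf"
    if suffix in (".csv", ".tsv", ".txt"):
        return "tabular"
    raise ValueError(f"cannot infer recording format from suffix {suffix!r}")
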