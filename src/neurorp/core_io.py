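"""Data model and file I/O for simultaneous EEG / fNIRS recordings.

The pipeline's in-memory currency is the :class:`Recording` (a channels ×
samples matrix plus rate and channel metadata) and the :class:`EventSchedule`
(timed protocol markers).  On disk, EEG travels as EDF, fNIRS as SNIRF
(HDF5), events as delimited text, and intermediate tensors as a lossless
``.npz`` container.

Readers never resample or filter: sample counts in equal sample counts out.
Event times are seconds from recording start; conversion to sample indices
is ``floor(onset * rate)`` with half-open ``[start, end)`` intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "EVENT_LABELS",
    "MODALITIES",
    "ChannelInfo",
    "Recording",
    "Event",
    "EventSchedule",
    "FormatError",
    "read_eeg_edf",
    "read_fnirs_snirf",
    "read_events_table",
    "write_events_table",
    "write_recording",
    "read_container",
]

#: Fixed class order used everywhere downstream (confusion matrices, softmax).
CLASS_LABELS = ("0-back", "2-back", "3-back", "rest")

#: Closed set of event labels a schedule may carry.
EVENT_LABELS = CLASS_LABELS + ("instruction",)

MODALITIES = ("eeg", "fnirs_od", "fnirs_hb")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class ChannelInfo:
    """Metadata for one recorded channel.

    Parameters
    ----------
    label
        Unique channel name (electrode or source-detector pair).
    role
        ``"eeg"`` for electrodes, ``"sd_pair"`` for optode pairs.
    wavelength
        Illumination wavelength in nm; present iff the channel belongs to a
        ``fnirs_od`` recording.
    source_detector_distance
        Optode separation in cm (fNIRS only).
    """

    label: str
    role: str = "eeg"
    wavelength: float | None = None
    source_detector_distance: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("eeg", "sd_pair"):
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.source_detector_distance is not None and self.source_detector_distance <= 0:
            raise ValueError("source_detector_distance must be > 0 cm")


@dataclass
class Recording:
    """A multichannel time series of one modality.

    ``data`` is channels × samples: µV for EEG, unitless optical-density
    change for ``fnirs_od``, µmol/L concentration change for ``fnirs_hb``.
    """

    data: np.ndarray
    rate: float
    channels: list[ChannelInfo]
    modality: str
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.rate <= 0:
            raise ValueError("rate must be > 0 Hz")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} ChannelInfo entries for {self.data.shape[0]} data rows"
            )
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate channel labels: {dupes}")
        if self.modality == "fnirs_od":
            if self.n_channels % 2:
                raise ValueError(
                    "fnirs_od needs an even channel count (two wavelengths per site)"
                )
            if any(c.wavelength is None for c in self.channels):
                raise ValueError("fnirs_od channels must carry a wavelength")
        else:
            if any(c.wavelength is not None for c in self.channels):
                raise ValueError(f"wavelength metadata is only valid for fnirs_od")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.rate

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def with_data(self, data: np.ndarray, rate: float | None = None) -> "Recording":
        """Copy of this recording with new samples (channel metadata kept)."""
        return replace(self, data=np.asarray(data, float), rate=self.rate if rate is None else rate)

    def time_slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples in the half-open window [start_s, end_s), as a view."""
        i0 = int(math.floor(start_s * self.rate))
        i1 = int(math.floor(end_s * self.rate))
        return self.data[:, i0:i1]


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    label: str


@dataclass
class EventSchedule:
    """Ordered, validated protocol markers for one series of one session."""

    events: list[Event]
    session_id: int = 0
    series_id: int = 0

    def __post_init__(self) -> None:
        prev_end = -math.inf
        prev_onset = -math.inf
        for ev in self.events:
            if ev.label not in EVENT_LABELS:
                raise ValueError(
                    f"unknown event label {ev.label!r}; allowed: {sorted(EVENT_LABELS)}"
                )
            if ev.duration <= 0:
                raise ValueError(f"event duration must be > 0 s (got {ev.duration})")
            if ev.onset < prev_onset:
                raise ValueError("event onsets must be non-decreasing")
            if ev.onset < prev_end - 1e-9:
                raise ValueError(
                    f"overlapping events at onset {ev.onset} s (previous ends {prev_end} s)"
                )
            prev_onset = ev.onset
            prev_end = ev.onset + ev.duration

    def __len__(self) -> int:
        return len(self.events)

    @property
    def span(self) -> float:
        """Seconds from the first onset to the last offset (0 if empty)."""
        if not self.events:
            return 0.0
        return self.events[-1].onset + self.events[-1].duration - self.events[0].onset


# ---------------------------------------------------------------------------
# EDF (EEG)
# ---------------------------------------------------------------------------

def read_eeg_edf(path) -> tuple[Recording, EventSchedule | None]:
    """Read an EDF/EDF+ file into an EEG Recording (µV).

    Annotations whose description is one of the protocol labels are returned
    as an :class:`EventSchedule`; ``None`` when there are no such annotations.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for malformed headers
        raise FormatError(f"unreadable EDF file {path}: {exc}") from exc
    labels = list(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise FormatError("EDF header field 'label': duplicate channel labels")
    data_uv = raw.get_data() * 1e6  # mne scales µV-dimensioned signals to V
    rec = Recording(
        data=data_uv,
        rate=float(raw.info["sfreq"]),
        channels=[ChannelInfo(label=l, role="eeg") for l in labels],
        modality="eeg",
    )
    events = [
        Event(float(on), float(du), str(de))
        for on, du, de in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
        if str(de) in EVENT_LABELS
    ]
    return rec, (EventSchedule(events=events) if events else None)


def _fit8(value: float) -> bytes:
    """Render a float into the 8-byte ASCII numeric field EDF headers use."""
    for fmt in ("%g", "%.5g", "%.4g", "%.3g", "%.2g", "%.1g"):
        s = fmt % value
        if len(s) <= 8:
            return s.ljust(8).encode("ascii")
    raise ValueError(f"cannot encode {value} in 8 ASCII bytes")


def _write_edf(rec: Recording, path) -> None:
    """Minimal plain-EDF writer: int16 samples, per-channel physical scaling.

    The record duration is chosen so that rate x duration is an integer
    number of samples; the recording must contain a whole number of records.
    """
    if rec.modality != "eeg":
        raise ValueError("EDF output is supported for modality 'eeg' only")
    frac = Fraction(rec.rate).limit_denominator(100)
    rec_dur = frac.denominator  # seconds per data record
    spr = frac.numerator  # samples per record per channel
    if rec_dur > 60:
        raise ValueError(f"rate {rec.rate} Hz needs an impractical EDF record duration")
    n_records, rem = divmod(rec.n_samples, spr)
    if rem:
        raise ValueError(
            f"recording length {rec.n_samples} is not a whole number of "
            f"{spr}-sample EDF records; pad or trim first"
        )
    nchan = rec.n_channels
    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.round((rec.data - pmin[:, None]) * gain[:, None] + dmin).astype("<i2")

    hdr = bytearray()
    hdr += b"0".ljust(8)
    hdr += b"X".ljust(80)  # patient id
    hdr += b"Startdate X".ljust(80)  # recording id
    hdr += b"01.01.00"
    hdr += b"00.00.00"
    hdr += str(256 * (nchan + 1)).ljust(8).encode()
    hdr += b" " * 44
    hdr += str(n_records).ljust(8).encode()
    hdr += _fit8(rec_dur)
    hdr += str(nchan).ljust(4).encode()
    for c in rec.channels:
        hdr += c.label[:16].ljust(16).encode("ascii")
    hdr += b" " * 80 * nchan  # transducer
    for _ in range(nchan):
        hdr += b"uV".ljust(8)
    for v in pmin:
        hdr += _fit8(v)
    for v in pmax:
        hdr += _fit8(v)
    for _ in range(nchan):
        hdr += _fit8(dmin)
    for _ in range(nchan):
        hdr += _fit8(dmax)
    hdr += b" " * 80 * nchan  # prefiltering
    for _ in range(nchan):
        hdr += str(spr).ljust(8).encode()
    hdr += b" " * 32 * nchan
    assert len(hdr) == 256 * (nchan + 1)

    # records: channel-major within each record
    blocks = digital.reshape(nchan, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        fh.write(blocks.tobytes())


# ---------------------------------------------------------------------------
# SNIRF (fNIRS)
# ---------------------------------------------------------------------------

def read_fnirs_snirf(path) -> Recording:
    """Read a SNIRF file into a ``fnirs_od`` Recording.

    Continuous-wave amplitude data (SNIRF dataType 1) are converted to
    optical-density change via ``-log(I / I0)`` with ``I0`` the per-channel
    temporal mean; processed ``dOD`` data pass through unchanged.  Channels
    are ordered site by site, ascending wavelength within a site.
    """
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise FormatError(f"{path}: missing /nirs group; not a SNIRF file")
        nirs = f["nirs"]
        if "data1" not in nirs:
            raise FormatError(f"{path}: missing /nirs/data1")
        d1 = nirs["data1"]
        ts = np.asarray(d1["dataTimeSeries"])  # T x nChan
        time = np.asarray(d1["time"]).ravel()
        if time.size == 2:  # [start, dt] short form
            rate = 1.0 / float(time[1])
            start = float(time[0])
        else:
            dt = np.diff(time)
            if dt.size and (dt.max() - dt.min()) > 1e-6 * dt.mean():
                raise FormatError(f"{path}: non-uniform /nirs/data1/time vector")
            rate = 1.0 / float(dt.mean())
            start = float(time[0])
        probe = nirs.get("probe")
        if probe is None or "wavelengths" not in probe:
            raise FormatError(f"{path}: missing /nirs/probe/wavelengths")
        wavelengths = np.asarray(probe["wavelengths"]).ravel()
        if wavelengths.size < 2:
            raise FormatError(
                f"{path}: only {wavelengths.size} wavelength(s); the Beer-Lambert "
                "conversion needs at least two per site"
            )
        if "sourcePos3D" in probe and "detectorPos3D" in probe:
            spos = np.asarray(probe["sourcePos3D"])
            dpos = np.asarray(probe["detectorPos3D"])
        elif "sourcePos2D" in probe and "detectorPos2D" in probe:
            spos = np.asarray(probe["sourcePos2D"])
            dpos = np.asarray(probe["detectorPos2D"])
        else:
            raise FormatError(
                f"{path}: probe geometry (sourcePos/detectorPos) absent; supply "
                "source-detector distances via configuration instead"
            )

        ml = []
        for name in sorted(k for k in d1 if k.startswith("measurementList")):
            g = d1[name]
            ml.append(
                (
                    int(np.asarray(g["sourceIndex"])),
                    int(np.asarray(g["detectorIndex"])),
                    int(np.asarray(g["wavelengthIndex"])),
                    int(np.asarray(g["dataType"])),
                    int(name[len("measurementList"):]),
                )
            )
        if len(ml) != ts.shape[1]:
            raise FormatError(
                f"{path}: {len(ml)} measurementList entries for {ts.shape[1]} data columns"
            )

    # order: by source-detector site, then wavelength
    order = sorted(ml, key=lambda m: (m[0], m[1], wavelengths[m[2] - 1]))
    data = np.empty((len(order), ts.shape[0]))
    channels = []
    for row, (src, det, wli, dtype, col) in enumerate(order):
        sig = ts[:, col - 1].astype(float)
        if dtype == 1:  # CW amplitude -> Delta OD against temporal-mean baseline
            i0 = sig.mean()
            if i0 <= 0:
                raise FormatError(f"{path}: non-positive amplitude in column {col}")
            sig = -np.log(sig / i0)
        data[row] = sig
        dist = float(np.linalg.norm(spos[src - 1] - dpos[det - 1]))
        channels.append(
            ChannelInfo(
                label=f"S{src}_D{det} {wavelengths[wli - 1]:.0f}nm",
                role="sd_pair",
                wavelength=float(wavelengths[wli - 1]),
                source_detector_distance=dist if dist > 0 else None,
            )
        )
    return Recording(data=data, rate=rate, channels=channels, modality="fnirs_od",
                     start_time=start)


def _write_snirf(rec: Recording, path) -> None:
    if rec.modality != "fnirs_od":
        raise ValueError("SNIRF output is supported for modality 'fnirs_od' only")
    wavelengths = sorted({c.wavelength for c in rec.channels})
    wl_index = {w: i + 1 for i, w in enumerate(wavelengths)}
    # one source-detector pair per site; consecutive channel pairs share a site
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        for k, v in (
            ("SubjectID", "synthetic"),
            ("MeasurementDate", "2000-01-01"),
            ("MeasurementTime", "00:00:00"),
            ("LengthUnit", "cm"),
            ("TimeUnit", "s"),
            ("FrequencyUnit", "Hz"),
        ):
            meta.create_dataset(k, data=v)
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=rec.data.T)
        d1.create_dataset(
            "time", data=rec.start_time + np.arange(rec.n_samples) / rec.rate
        )
        n_sites = rec.n_channels // len(wavelengths)
        spos = np.zeros((n_sites, 3))
        dpos = np.zeros((n_sites, 3))
        spos[:, 1] = np.arange(n_sites) * 10.0  # lay sites out along y
        dpos[:, 1] = np.arange(n_sites) * 10.0
        for row, c in enumerate(rec.channels):
            site = row // len(wavelengths)
            dpos[site, 0] = c.source_detector_distance or 3.0
            g = d1.create_group(f"measurementList{row + 1}")
            g.create_dataset("sourceIndex", data=site + 1)
            g.create_dataset("detectorIndex", data=site + 1)
            g.create_dataset("wavelengthIndex", data=wl_index[c.wavelength])
            g.create_dataset("dataType", data=99999)  # processed
            g.create_dataset("dataTypeLabel", data="dOD")
            g.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wavelengths, float))
        probe.create_dataset("sourcePos3D", data=spos)
        probe.create_dataset("detectorPos3D", data=dpos)


# ---------------------------------------------------------------------------
# Events table and lossless container
# ---------------------------------------------------------------------------

def read_events_table(path) -> EventSchedule:
    """Read a delimited text file with columns onset, duration, label."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"onset", "duration", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"events table needs columns {sorted(required)}, got {list(df.columns)}")
    bad = sorted(set(df["label"].astype(str)) - set(EVENT_LABELS))
    if bad:
        raise FormatError(
            f"unknown event label(s) {bad}; allowed labels: {sorted(EVENT_LABELS)}"
        )
    events = [
        Event(float(r.onset), float(r.duration), str(r.label)) for r in df.itertuples()
    ]
    sess = int(df["session_id"].iloc[0]) if "session_id" in df and len(df) else 0
    series = int(df["series_id"].iloc[0]) if "series_id" in df and len(df) else 0
    return EventSchedule(events=events, session_id=sess, series_id=series)


def write_events_table(schedules, path) -> None:
    """Write one or more EventSchedules to tab-separated text."""
    if isinstance(schedules, EventSchedule):
        schedules = [schedules]
    rows = [
        {
            "onset": ev.onset,
            "duration": ev.duration,
            "label": ev.label,
            "session_id": s.session_id,
            "series_id": s.series_id,
        }
        for s in schedules
        for ev in s.events
    ]
    pd.DataFrame(rows, columns=["onset", "duration", "label", "session_id", "series_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_recording(rec: Recording, path, format: str) -> None:
    """Write a Recording as ``edf``, ``snirf`` or the lossless ``container``.

    The container (NumPy ``.npz``) is bit-exact; EDF quantizes to 16 bits.
    """
    if not isinstance(rec, Recording):
        raise TypeError("rec must be a Recording")
    if format == "edf":
        _write_edf(rec, path)
    elif format == "snirf":
        _write_snirf(rec, path)
    elif format == "container":
        np.savez(
            path,
            data=rec.data,
            rate=rec.rate,
            modality=rec.modality,
            start_time=rec.start_time,
            labels=np.array(rec.labels),
            roles=np.array([c.role for c in rec.channels]),
            wavelengths=np.array(
                [c.wavelength if c.wavelength is not None else np.nan for c in rec.channels]
            ),
            distances=np.array(
                [
                    c.source_detector_distance
                    if c.source_detector_distance is not None
                    else np.nan
                    for c in rec.channels
                ]
            ),
        )
    else:
        raise ValueError(f"unknown format {format!r}; use edf, snirf or container")


def read_container(path) -> Recording:
    """Read a Recording back from the lossless ``.npz`` container."""
    with np.load(path, allow_pickle=False) as z:
        channels = [
            ChannelInfo(
                label=str(l),
                role=str(r),
                wavelength=None if np.isnan(w) else float(w),
                source_detector_distance=None if np.isnan(d) else float(d),
            )
            for l, r, w, d in zip(z["labels"], z["roles"], z["wavelengths"], z["distances"])
        ]
        return Recording(
            data=z["data"],
            rate=float(z["rate"]),
            channels=channels,
            modality=str(z["modality"]),
            start_time=float(z["start_time"]),
        )
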