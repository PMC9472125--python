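"""Pre-processing: resampling, zero-phase filtering, Beer–Lambert conversion,
four-class labeling, outlier rejection and normalization.

The EEG path is: downsample to 200 Hz, zero-phase 6th-order Butterworth
bandpass 1–40 Hz.  The fNIRS path is: optical density → modified
Beer–Lambert conversion to ΔHbO/ΔHbR → downsample to 10 Hz → zero-phase
6th-order Butterworth low-pass at 0.2 Hz.

Zero phase is realized as forward-backward (cascaded second-order sections)
filtering, which squares the magnitude response and cancels phase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core_io import CLASS_LABELS, EventSchedule, Recording

__all__ = [
    "HemoRecording",
    "Segment",
    "LabeledSegments",
    "resample",
    "bandpass_zero_phase",
    "lowpass_zero_phase",
    "mbll_convert",
    "label_segments",
    "reject_outliers",
    "normalize",
    "fit_normalizer",
]


@dataclass
class HemoRecording:
    """Oxy-/deoxy-hemoglobin concentration changes (µmol/L) per site."""

    hbo: np.ndarray  # sites x samples
    hbr: np.ndarray
    rate: float
    site_labels: list[str]

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, float)
        self.hbr = np.asarray(self.hbr, float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have the same shape")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    @property
    def n_sites(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def stacked(self) -> np.ndarray:
        """HbO rows followed by HbR rows, as one channels x samples matrix."""
        return np.vstack([self.hbo, self.hbr])


@dataclass(frozen=True)
class Segment:
    start: float  # seconds
    end: float
    label: str
    session_id: int = 0
    series_id: int = 0


@dataclass
class LabeledSegments:
    """Non-overlapping labeled time intervals shared by both modalities."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        for seg in self.segments:
            if seg.label not in CLASS_LABELS:
                raise ValueError(f"segment label {seg.label!r} outside {CLASS_LABELS}")
            if seg.end <= seg.start:
                raise ValueError("segment end must exceed start")
        ordered = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError(f"segments overlap at {b.start} s")

    def __len__(self) -> int:
        return len(self.segments)

    def by_label(self, label: str) -> list[Segment]:
        return [s for s in self.segments if s.label == label]


def resample(rec: Recording, target_rate: float) -> Recording:
    """Downsample with anti-alias filtering (polyphase FIR, Kaiser window).

    The rational resampling factor is the reduced fraction of
    ``target_rate / rate``; upsampling is refused.  ``target_rate == rate``
    is the identity.
    """
    if target_rate > rec.rate:
        raise ValueError(
            f"upsampling ({rec.rate} -> {target_rate} Hz) is not supported"
        )
    if math.isclose(target_rate, rec.rate):
        return rec.with_data(rec.data.copy())
    frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.data, up, down, axis=1, window=("kaiser", 8.6))
    return rec.with_data(out, rate=target_rate)


def _zero_phase_sos(rec: Recording, sos: np.ndarray) -> Recording:
    # odd-reflective edge padding of 3x the filter order bounds edge transients
    padlen = min(3 * 2 * sos.shape[0], rec.n_samples - 1)
    out = signal.sosfiltfilt(sos, rec.data, axis=1, padtype="odd", padlen=padlen)
    return rec.with_data(out)


def bandpass_zero_phase(
    rec: Recording, low: float = 1.0, high: float = 40.0, order: int = 6
) -> Recording:
    """Zero-phase Butterworth bandpass (default 6th order, 1–40 Hz)."""
    nyq = rec.rate / 2
    if not (0 < low < high < nyq):
        raise ValueError(f"band [{low}, {high}] Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    return _zero_phase_sos(rec, sos)


def lowpass_zero_phase(rec: Recording, cutoff: float = 0.2, order: int = 6) -> Recording:
    """Zero-phase Butterworth low-pass (default 6th order, 0.2 Hz)."""
    nyq = rec.rate / 2
    if not (0 < cutoff < nyq):
        raise ValueError(f"cutoff {cutoff} Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=rec.rate, output="sos")
    return _zero_phase_sos(rec, sos)


def mbll_convert(
    od: Recording,
    extinction: dict[float, tuple[float, float]] | None = None,
    dpf: float = 6.0,
    distance: float | None = None,
    baseline: str = "none",
) -> HemoRecording:
    """Invert the modified Beer–Lambert law per source-detector site.

    For each site with optical-density changes at two wavelengths,

        [ΔHbO; ΔHbR] = (E · d · DPF)⁻¹ · [ΔOD_λ1; ΔOD_λ2]

    where ``E`` holds the extinction coefficients (L/(µmol·cm)), ``d`` the
    source-detector distance (cm) and DPF the differential pathlength
    factor.  ``baseline="mean"`` re-references each OD channel to its
    temporal mean first (raw amplitude-derived OD is already referenced at
    read time, so the default leaves the data untouched).
    """
    if od.modality != "fnirs_od":
        raise ValueError("mbll_convert expects a fnirs_od recording")
    if extinction is None:
        from .synthgen import DEFAULT_EXTINCTION

        extinction = DEFAULT_EXTINCTION
    data = od.data
    if baseline == "mean":
        data = data - data.mean(axis=1, keepdims=True)
    elif baseline != "none":
        raise ValueError("baseline must be 'none' or 'mean'")

    n_sites = od.n_channels // 2
    hbo = np.empty((n_sites, od.n_samples))
    hbr = np.empty_like(hbo)
    site_labels = []
    for s in range(n_sites):
        ch1, ch2 = od.channels[2 * s], od.channels[2 * s + 1]
        d = distance or ch1.source_detector_distance
        if d is None or d <= 0:
            raise ValueError(f"no source-detector distance for site {ch1.label}")
        E = np.empty((2, 2))
        for row, ch in enumerate((ch1, ch2)):
            if ch.wavelength not in extinction:
                raise ValueError(
                    f"no extinction coefficients for {ch.wavelength} nm; "
                    f"known wavelengths: {sorted(extinction)}"
                )
            E[row] = extinction[ch.wavelength]
        A = E * d * dpf
        cond = np.linalg.cond(A)
        if cond > 1e8:
            raise ValueError(
                f"extinction matrix for site {ch1.label} is numerically singular "
                f"(condition number {cond:.3g}); check wavelength pairing"
            )
        conc = np.linalg.solve(A, data[2 * s : 2 * s + 2])
        hbo[s], hbr[s] = conc
        site_labels.append(ch1.label.split()[0])
    return HemoRecording(hbo=hbo, hbr=hbr, rate=od.rate, site_labels=site_labels)


def label_segments(
    schedules: list[EventSchedule] | EventSchedule,
    classes: tuple[str, ...] = CLASS_LABELS,
) -> LabeledSegments:
    """Label each 40 s task block with its n-back class and each rest period
    as rest; instruction periods are excluded."""
    if isinstance(schedules, EventSchedule):
        schedules = [schedules]
    segs = [
        Segment(ev.onset, ev.onset + ev.duration, ev.label, s.session_id, s.series_id)
        for s in schedules
        for ev in s.events
        if ev.label in classes
    ]
    return LabeledSegments(segments=segs)


def reject_outliers(
    windows: np.ndarray, z_max: float = 5.0
) -> tuple[np.ndarray, dict]:
    """Drop windows containing extreme samples under a robust z-score.

    Per-channel median and MAD are computed over all windows jointly; a
    window is rejected when any sample's ``|x - median| / (1.4826 * MAD)``
    exceeds ``z_max``.  Returns the surviving windows and a log dict with
    the rejected indices.
    """
    windows = np.asarray(windows, float)
    if windows.ndim != 3:
        raise ValueError("windows must be (n_windows, channels, samples)")
    if np.isinf(z_max):
        return windows, {"n_rejected": 0, "rejected_indices": [], "z_max": z_max}
    med = np.median(windows, axis=(0, 2), keepdims=True)
    mad = np.median(np.abs(windows - med), axis=(0, 2), keepdims=True)
    scale = 1.4826 * np.where(mad > 0, mad, 1.0)
    z = np.abs(windows - med) / scale
    peak = z.max(axis=(1, 2))
    keep = peak <= z_max
    if not keep.any():
        raise ValueError(
            f"all {len(windows)} windows rejected at z_max={z_max}; "
            "review the threshold"
        )
    rejected = np.flatnonzero(~keep)
    return windows[keep], {
        "n_rejected": int(rejected.size),
        "rejected_indices": rejected.tolist(),
        "z_max": z_max,
    }


def fit_normalizer(windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and standard deviation over training windows."""
    windows = np.asarray(windows, float)
    mean = windows.mean(axis=(0, 2))
    sd = windows.std(axis=(0, 2))
    zero = np.flatnonzero(sd < 1e-15)
    if zero.size:
        raise ValueError(f"zero-variance channel(s) {zero.tolist()}; cannot z-score")
    return mean, sd


def normalize(
    windows: np.ndarray, stats: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Z-score windows per channel with statistics from the training fold.

    ``stats`` must come from :func:`fit_normalizer` on training data only;
    applying the same statistics to held-out folds keeps the transform
    leakage-free.
    """
    mean, sd = stats
    windows = np.asarray(windows, float)
    return (windows - mean[None, :, None]) / sd[None, :, None]
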