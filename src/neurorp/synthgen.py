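"""Synthetic simultaneous EEG + fNIRS n-back sessions.

The generator emulates the acquisition protocol the pipeline targets: three
sessions, each containing a randomized sequence of 0-back, 2-back and 3-back
series; every series is 2 s of task instruction, a 40 s task block of twenty
2 s stimuli, and 20 s of rest (62 s total).  EEG is produced at 1,000 Hz
over 30 channels, fNIRS as two-wavelength optical densities at 10.4 Hz over
16 source-detector sites.

Class information is injected through standard working-memory physiology:

* EEG — frontal-midline theta (≈6 Hz) amplitude grows and parietal alpha
  (≈9.5 Hz) amplitude shrinks monotonically with n-back load, scaled by
  ``effect_size``; pink (1/f) background, 50 Hz line noise and slow drift
  are added on top.
* fNIRS — each task block drives a latent ΔHbO boxcar convolved with a
  double-gamma hemodynamic response (peak ≈6 s, undershoot ≈16 s) whose
  amplitude grows with load; ΔHbR ≈ −ΔHbO/3.  Mayer waves (0.1 Hz),
  respiration (0.25 Hz) and cardiac (1.1 Hz) oscillations plus drift and
  white noise are superimposed, and optical densities are produced with the
  forward modified Beer–Lambert law at 760/850 nm.

These signatures are modeling choices that make the labels recoverable;
they are not claims about any particular dataset.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from .core_io import ChannelInfo, Event, EventSchedule, Recording

__all__ = [
    "ProtocolSpec",
    "SubjectProfile",
    "DEFAULT_EXTINCTION",
    "build_schedule",
    "simulate_eeg",
    "simulate_fnirs",
    "simulate_subject",
]

#: Extinction coefficients in L / (µmol · cm), rows = wavelength, cols = (HbO, HbR).
#: Values follow the commonly used compiled in-vitro hemoglobin spectra.
DEFAULT_EXTINCTION = {
    760.0: (1.4866e-3, 3.8437e-3),
    850.0: (2.5264e-3, 1.7986e-3),
}

#: Relative n-back load factors used to scale class-dependent components.
LOAD = {"0-back": 0.5, "2-back": 1.0, "3-back": 1.5}


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing structure of the n-back experiment."""

    n_sessions: int = 3
    series_per_condition_per_session: int = 3
    stimuli_per_series: int = 20
    stimulus_duration: float = 2.0
    instruction_duration: float = 2.0
    rest_duration: float = 20.0
    conditions: tuple[str, ...] = ("0-back", "2-back", "3-back")

    def __post_init__(self) -> None:
        for name in ("n_sessions", "series_per_condition_per_session", "stimuli_per_series"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("stimulus_duration", "instruction_duration", "rest_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 s")

    @property
    def task_duration(self) -> float:
        """Task-period length: stimuli per series x stimulus duration."""
        return self.stimuli_per_series * self.stimulus_duration

    @property
    def series_duration(self) -> float:
        return self.instruction_duration + self.task_duration + self.rest_duration

    @property
    def trials_per_condition(self) -> int:
        return (
            self.n_sessions
            * self.series_per_condition_per_session
            * self.stimuli_per_series
        )


@dataclass(frozen=True)
class SubjectProfile:
    """Signal-level parameters of one simulated subject.

    ``noise_levels`` amplitudes are µV for EEG sources and µmol/L for
    hemodynamic sources; ``effect_size`` scales every class-dependent
    component (0 erases all class information).
    """

    seed: int = 0
    eeg_channels: int = 30
    fnirs_sites: int = 16
    eeg_rate: float = 1000.0
    fnirs_rate: float = 10.4
    effect_size: float = 1.0
    wavelengths: tuple[float, float] = (760.0, 850.0)
    dpf: float = 6.0
    source_detector_distance: float = 3.0  # cm
    noise_levels: dict = field(
        default_factory=lambda: {
            "pink": 8.0,  # µV, broadband 1/f EEG background
            "line": 1.0,  # µV, 50 Hz mains
            "drift": 2.0,  # µV (EEG) / µmol/L-scaled (fNIRS) linear drift
            "cardiac": 0.03,  # µmol/L, ~1.1 Hz
            "respiration": 0.05,  # µmol/L, ~0.25 Hz
            "mayer": 0.08,  # µmol/L, ~0.1 Hz
            "white_od": 0.02,  # µmol/L-equivalent sensor noise
        }
    )

    def __post_init__(self) -> None:
        if self.eeg_rate <= 0 or self.fnirs_rate <= 0:
            raise ValueError("sampling rates must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def build_schedule(spec: ProtocolSpec, seed: int) -> list[EventSchedule]:
    """Build per-series event schedules for all sessions.

    Within each session the series order is a seeded permutation of
    condition × repetition.  Consecutive series are laid out back to back on
    a common time axis, one schedule per series.
    """
    rng = np.random.default_rng(seed)
    schedules: list[EventSchedule] = []
    t = 0.0
    for session in range(spec.n_sessions):
        cells = [
            cond
            for cond in spec.conditions
            for _ in range(spec.series_per_condition_per_session)
        ]
        order = rng.permutation(len(cells))
        for k, idx in enumerate(order):
            cond = cells[idx]
            events = [
                Event(t, spec.instruction_duration, "instruction"),
                Event(t + spec.instruction_duration, spec.task_duration, cond),
                Event(
                    t + spec.instruction_duration + spec.task_duration,
                    spec.rest_duration,
                    "rest",
                ),
            ]
            schedules.append(EventSchedule(events=events, session_id=session, series_id=k))
            t += spec.series_duration
    return schedules


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int) -> np.ndarray:
    """1/f-amplitude noise, unit standard deviation per channel."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, freqs[1])), 0.0)
    spectrum = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * scale
    x = np.fft.irfft(spectrum, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _oscillation(
    rng: np.random.Generator, freq: float, rate: float, envelope: np.ndarray
) -> np.ndarray:
    """Narrow-band oscillation with random phase and slow amplitude jitter."""
    n = envelope.size
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    # slow multiplicative jitter so the rhythm is not a pure tone
    jitter = 1.0 + 0.2 * np.interp(
        np.arange(n), np.linspace(0, n - 1, 50), rng.standard_normal(50)
    )
    return envelope * jitter * np.sin(2 * np.pi * freq * t + phase)


def _class_envelope(
    schedules: list[EventSchedule], rate: float, n: int, gains: dict[str, float]
) -> np.ndarray:
    """Piecewise-constant gain over time: ``gains[label]`` inside task blocks."""
    env = np.ones(n)
    for sched in schedules:
        for ev in sched.events:
            if ev.label in gains:
                i0 = int(np.floor(ev.onset * rate))
                i1 = int(np.floor((ev.onset + ev.duration) * rate))
                env[i0:i1] = gains[ev.label]
    return env


def simulate_eeg(
    schedules: list[EventSchedule], profile: SubjectProfile
) -> tuple[Recording, list[EventSchedule]]:
    """Simulate the EEG recording for a full set of series schedules.

    Returns the recording and the (unchanged) schedules as ground truth.
    """
    rate = profile.eeg_rate
    if rate < 2 * 50.0:
        raise ValueError("eeg_rate below Nyquist for the 50 Hz line-noise component")
    rng = np.random.default_rng(profile.seed)
    total_s = max(s.events[-1].onset + s.events[-1].duration for s in schedules)
    n = int(round(total_s * rate))
    nch = profile.eeg_channels
    nl = profile.noise_levels

    data = nl.get("pink", 0.0) * _pink_noise(rng, nch, n)

    # spatial weight profiles: theta frontal, alpha parietal (front = low index)
    ch_pos = np.linspace(0, 1, nch)
    theta_w = np.exp(-((ch_pos - 0.15) ** 2) / (2 * 0.2**2))
    alpha_w = np.exp(-((ch_pos - 0.85) ** 2) / (2 * 0.2**2))

    e = profile.effect_size
    theta_gain = {c: 1.0 + LOAD[c] * e for c in LOAD}
    alpha_gain = {c: 1.0 / (1.0 + LOAD[c] * e) for c in LOAD}
    theta_env = 3.0 * _class_envelope(schedules, rate, n, theta_gain)
    alpha_env = 3.0 * _class_envelope(schedules, rate, n, alpha_gain)

    theta = _oscillation(rng, 6.0, rate, theta_env)
    alpha = _oscillation(rng, 9.5, rate, alpha_env)
    data += theta_w[:, None] * theta + alpha_w[:, None] * alpha

    t = np.arange(n) / rate
    if nl.get("line", 0.0):
        data += nl["line"] * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    if nl.get("drift", 0.0) and n:
        data += nl["drift"] * rng.standard_normal(nch)[:, None] * (t / max(t[-1], 1))

    channels = [ChannelInfo(label=f"EEG{i + 1:02d}", role="eeg") for i in range(nch)]
    rec = Recording(data=data, rate=rate, channels=channels, modality="eeg")
    return rec, schedules


def double_gamma_hrf(rate: float, duration_s: float = 30.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak ~6 s, undershoot ~16 s).

    Normalized to unit peak; sampled at ``rate``.
    """
    t = np.arange(0, duration_s, 1.0 / rate)
    peak = gamma_dist.pdf(t, 6.0)
    undershoot = gamma_dist.pdf(t, 16.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def simulate_fnirs(
    schedules: list[EventSchedule], profile: SubjectProfile
) -> tuple[Recording, "np.ndarray", "np.ndarray"]:
    """Simulate two-wavelength optical densities plus ground-truth ΔHbO/ΔHbR.

    Returns ``(od_recording, hbo, hbr)`` where ``hbo``/``hbr`` are the latent
    sites × samples concentration changes (µmol/L) before sensor noise; the
    optical densities are the forward modified Beer–Lambert transform of the
    noisy concentrations.
    """
    for wl in profile.wavelengths:
        if wl not in DEFAULT_EXTINCTION:
            raise ValueError(
                f"no extinction coefficients for {wl} nm; known: "
                f"{sorted(DEFAULT_EXTINCTION)}"
            )
    rate = profile.fnirs_rate
    rng = np.random.default_rng(profile.seed + 1)
    total_s = max(s.events[-1].onset + s.events[-1].duration for s in schedules)
    n = int(round(total_s * rate))
    nsites = profile.fnirs_sites
    nl = profile.noise_levels
    e = profile.effect_size

    # latent neural drive: per-class-amplitude boxcar over each task block,
    # modulated by slow trial-to-trial variability that scales with the
    # drive itself (activity-dependent vascular fluctuation)
    drive = np.zeros(n)
    for sched in schedules:
        for ev in sched.events:
            if ev.label in LOAD:
                i0 = int(np.floor(ev.onset * rate))
                i1 = int(np.floor((ev.onset + ev.duration) * rate))
                drive[i0:i1] = LOAD[ev.label] * e
    hrf = double_gamma_hrf(rate)
    site_gain = 0.6 + 0.8 * rng.random(nsites)  # heterogeneous regional involvement
    # plateau of a sustained block ~ 0.4 µmol/L per unit load x effect,
    # keeping ΔHbO in the physiologic sub-2-µmol/L range
    amp = 0.4 / hrf.sum()
    hbo = np.empty((nsites, n))
    if n:
        k = max(int(rate / 0.3), 1)  # ~0.3 Hz knee for the slow modulation
        kernel = np.hanning(2 * k + 1)
        kernel /= kernel.sum()
        for s in range(nsites):
            slow = np.convolve(rng.standard_normal(n), kernel, mode="same")
            sd = slow.std() or 1.0
            modulated = drive * (1.0 + 0.6 * slow / sd)
            hbo[s] = site_gain[s] * amp * fftconvolve(modulated, hrf)[:n]
    hbr = -hbo / 3.0

    hbo_noisy = hbo.copy()
    hbr_noisy = hbr.copy()
    for freq, key in ((1.1, "cardiac"), (0.25, "respiration"), (0.1, "mayer")):
        amp = nl.get(key, 0.0)
        if amp:
            for s in range(nsites):
                osc = _oscillation(rng, freq, rate, amp * np.ones(n))
                hbo_noisy[s] += osc
                hbr_noisy[s] += 0.3 * osc
    if nl.get("drift", 0.0) and n:
        t = np.arange(n) / rate
        hbo_noisy += 0.05 * nl["drift"] * rng.standard_normal(nsites)[:, None] * (
            t / max(t[-1], 1)
        )
    if nl.get("white_od", 0.0):
        hbo_noisy += nl["white_od"] * rng.standard_normal((nsites, n))
        hbr_noisy += nl["white_od"] / 3.0 * rng.standard_normal((nsites, n))

    # forward modified Beer-Lambert: dOD_wl = (e_HbO*HbO + e_HbR*HbR) * d * DPF
    pathlength = profile.source_detector_distance * profile.dpf
    data = np.empty((2 * nsites, n))
    channels = []
    for s in range(nsites):
        for w, wl in enumerate(sorted(profile.wavelengths)):
            e_hbo, e_hbr = DEFAULT_EXTINCTION[wl]
            data[2 * s + w] = (e_hbo * hbo_noisy[s] + e_hbr * hbr_noisy[s]) * pathlength
            channels.append(
                ChannelInfo(
                    label=f"S{s + 1}_D{s + 1} {wl:.0f}nm",
                    role="sd_pair",
                    wavelength=wl,
                    source_detector_distance=profile.source_detector_distance,
                )
            )
    rec = Recording(data=data, rate=rate, channels=channels, modality="fnirs_od")
    return rec, hbo, hbr


def simulate_subject(
    spec: ProtocolSpec | None = None, profile: SubjectProfile | None = None
):
    """Convenience wrapper: schedules + EEG + fNIRS for one subject.

    Returns ``(schedules, eeg_recording, od_recording, hbo, hbr)``.
    """
    spec = spec or ProtocolSpec()
    profile = profile or SubjectProfile()
    schedules = build_schedule(spec, profile.seed)
    eeg, _ = simulate_eeg(schedules, profile)
    od, hbo, hbr = simulate_fnirs(schedules, profile)
    return schedules, eeg, od, hbo, hbr
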