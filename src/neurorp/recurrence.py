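"""Recurrence plots: delay embedding, phase-space distances, thresholding,
and windowed RP image sequences.

A scalar series ``x`` is delay-embedded into phase-space vectors

    x_i = (x_i, x_{i+d}, ..., x_{i+(m-1)d})

with dimension ``m`` and delay ``d``; multichannel windows stack all
channels into one state vector per time point.  The recurrence matrix marks
every pair of times whose states lie within a radius ``epsilon``:

    R(i, j) = 1  if  ||x(i) - x(j)|| <= epsilon  else 0.

By default ``epsilon`` is interpreted as a fraction (0.1) of the window's
maximum pairwise distance, making binary plots invariant under positive
rescaling of the signal; an absolute mode keeps the literal threshold.
Labeled signal segments are cut into 5 s windows with 20 % overlap; within
each window the samples are strided (step 10 for EEG by default) before
embedding, so a 5 s, 200 Hz EEG window yields a 100 x 100 image and a 5 s,
10 Hz fNIRS window a 50 x 50 image — no cross-modality downsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import CLASS_LABELS, Recording

__all__ = [
    "EmbeddingConfig",
    "RPConfig",
    "StateTrajectory",
    "RPSequence",
    "HybridSample",
    "RPSample",
    "embed",
    "check_embedding",
    "distance_matrix",
    "recurrence_matrix",
    "window_rp_sequence",
    "pair_hybrid",
    "chunk_sequences",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding parameters (dimension ``m``, delay ``d`` in samples).

    ``n`` optionally declares the underlying system dimension so the
    sufficiency condition ``m >= 2n + 1`` can be checked.
    """

    m: int = 1
    d: int = 1
    n: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.d < 1:
            raise ValueError("delay d must be >= 1 sample")


@dataclass(frozen=True)
class RPConfig:
    """Windowing and thresholding parameters for RP construction."""

    window_s: float = 5.0
    overlap: float = 0.2
    step: int = 10  # within-window subsampling stride (EEG default; use 1 for fNIRS)
    epsilon: float = 0.1
    epsilon_mode: str = "fraction_of_max_distance"  # or "absolute"
    output_mode: str = "binary"  # or "grayscale"
    channel_normalize: bool = True  # z-score each channel within the window

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.epsilon_mode not in ("fraction_of_max_distance", "absolute"):
            raise ValueError("epsilon_mode must be fraction_of_max_distance or absolute")
        if self.output_mode not in ("binary", "grayscale"):
            raise ValueError("output_mode must be binary or grayscale")


@dataclass
class StateTrajectory:
    """Delay-embedded phase-space trajectory: T x (m * channels) matrix."""

    states: np.ndarray
    window_bounds: tuple[float, float] | None = None


@dataclass
class RPSequence:
    """Chronologically ordered stack of RP images for one labeled segment."""

    images: np.ndarray  # (n_windows, T, T)
    label: str
    modality: str
    window_s: float
    overlap: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be a stack of square matrices")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label {self.label!r} outside {CLASS_LABELS}")

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass
class RPSample:
    """One classifier sample: T_seq consecutive RP images with one label."""

    x: np.ndarray  # (t_seq, T, T)
    label: str
    provenance: dict = field(default_factory=dict)


@dataclass
class HybridSample:
    """Positionally aligned EEG/fNIRS RP window pairs sharing one label."""

    eeg: np.ndarray  # (n_windows, T_e, T_e)
    fnirs: np.ndarray  # (n_windows, T_f, T_f)
    label: str
    window_s: float
    overlap: float
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.eeg.shape[0]


def embed(series: np.ndarray, cfg: EmbeddingConfig) -> StateTrajectory:
    """Delay-embed a (possibly multichannel) window.

    ``series`` is 1-D (samples) or 2-D (channels x samples).  Row ``i`` of
    the result concatenates, channel by channel, the ``m`` delayed copies
    at delays 0, d, ..., (m-1)d.
    """
    x = np.atleast_2d(np.asarray(series, float))
    n_ch, length = x.shape
    m, d = cfg.m, cfg.d
    t = length - (m - 1) * d
    if t < 1:
        raise ValueError(
            f"window of {length} samples too short for m={m}, d={d}; "
            f"needs >= {(m - 1) * d + 1}"
        )
    states = np.empty((t, n_ch * m))
    for c in range(n_ch):
        for k in range(m):
            states[:, c * m + k] = x[c, k * d : k * d + t]
    return StateTrajectory(states=states)


def check_embedding(cfg: EmbeddingConfig) -> bool:
    """Warn (never fail) when ``m < 2n + 1`` for a declared system dimension.

    Returns True when the sufficiency condition holds or no ``n`` is given.
    """
    if cfg.n is None:
        return True
    if cfg.m >= 2 * cfg.n + 1:
        return True
    warnings.warn(
        f"embedding dimension m={cfg.m} < 2n+1 = {2 * cfg.n + 1}; the "
        "reconstruction may not capture the full system",
        stacklevel=2,
    )
    return False


def distance_matrix(traj: StateTrajectory) -> np.ndarray:
    """Pairwise Euclidean distances D(i, j) = ||x(i) - x(j)||₂.

    Symmetric with zero diagonal by construction (elementwise differences,
    identical arithmetic to a direct double loop).
    """
    s = traj.states
    if s.shape[0] < 2:
        raise ValueError("need at least 2 phase-space states")
    diff = s[:, None, :] - s[None, :, :]
    return np.sqrt((diff * diff).sum(axis=-1))


def recurrence_matrix(D: np.ndarray, cfg: RPConfig) -> np.ndarray:
    """Threshold a distance matrix into an RP image.

    Binary mode: 1 where ``D <= eps`` with ``eps = epsilon * max(D)`` in
    fraction mode or ``epsilon`` literally in absolute mode.  Grayscale
    mode returns ``1 - D / max(D)`` (all ones for a constant window).
    """
    D = np.asarray(D, float)
    dmax = D.max()
    if cfg.output_mode == "grayscale":
        return np.ones_like(D) if dmax == 0 else 1.0 - D / dmax
    eps = cfg.epsilon * dmax if cfg.epsilon_mode == "fraction_of_max_distance" else cfg.epsilon
    return (D <= eps).astype(np.float32)


def window_rp_sequence(
    rec: Recording,
    label: str,
    ecfg: EmbeddingConfig,
    rcfg: RPConfig,
    start_s: float | None = None,
    end_s: float | None = None,
    data: np.ndarray | None = None,
    provenance: dict | None = None,
) -> RPSequence:
    """Cut a labeled segment into overlapping windows and build one RP each.

    Windows are ``round(window_s * rate)`` samples long and advance by
    ``round(window_s * (1 - overlap) * rate)``; within each window samples
    are strided by ``rcfg.step`` before embedding, and all channels are
    stacked into the state vector (z-scored per channel within the window
    when ``rcfg.channel_normalize``).
    """
    if data is None:
        if start_s is None:
            data = rec.data
        else:
            data = rec.time_slice(start_s, end_s)
    rate = rec.rate
    w = int(round(rcfg.window_s * rate))
    s = int(round(rcfg.window_s * (1 - rcfg.overlap) * rate))
    s = max(s, 1)
    n = data.shape[1]
    if n < w:
        raise ValueError(
            f"segment of {n} samples shorter than one {w}-sample window"
        )
    n_win = (n - w) // s + 1
    images = []
    for k in range(n_win):
        win = data[:, k * s : k * s + w : rcfg.step]
        if rcfg.channel_normalize:
            mu = win.mean(axis=1, keepdims=True)
            sd = win.std(axis=1, keepdims=True)
            win = (win - mu) / np.where(sd > 0, sd, 1.0)
        traj = embed(win, ecfg)
        images.append(recurrence_matrix(distance_matrix(traj), rcfg))
    return RPSequence(
        images=np.stack(images),
        label=label,
        modality=rec.modality,
        window_s=rcfg.window_s,
        overlap=rcfg.overlap,
        provenance=provenance or {},
    )


def pair_hybrid(eeg_seq: RPSequence, fnirs_seq: RPSequence) -> HybridSample:
    """Align EEG and fNIRS RP windows from the same labeled segment.

    Both sequences must share the window grid in seconds (window length and
    overlap); a length mismatch from sampling-rate rounding is resolved by
    truncating to the shorter sequence, with a warning.
    """
    if eeg_seq.label != fnirs_seq.label:
        raise ValueError(
            f"label mismatch: {eeg_seq.label!r} vs {fnirs_seq.label!r}"
        )
    if (eeg_seq.window_s, eeg_seq.overlap) != (fnirs_seq.window_s, fnirs_seq.overlap):
        raise ValueError("EEG and fNIRS sequences use different window grids")
    n_e, n_f = len(eeg_seq), len(fnirs_seq)
    n = min(n_e, n_f)
    if n_e != n_f:
        warnings.warn(
            f"window-count mismatch ({n_e} EEG vs {n_f} fNIRS); truncating to {n}",
            stacklevel=2,
        )
    return HybridSample(
        eeg=eeg_seq.images[:n],
        fnirs=fnirs_seq.images[:n],
        label=eeg_seq.label,
        window_s=eeg_seq.window_s,
        overlap=eeg_seq.overlap,
        provenance={**fnirs_seq.provenance, **eeg_seq.provenance},
    )


def chunk_sequences(
    seq: RPSequence | HybridSample, t_seq: int = 4
) -> list[RPSample]:
    """Split a window sequence into non-overlapping runs of ``t_seq`` windows.

    Each run becomes one classifier sample; trailing windows that do not
    fill a run are dropped.  Hybrid inputs yield samples whose ``x`` is an
    (eeg, fnirs) tuple.
    """
    if t_seq < 1:
        raise ValueError("t_seq must be >= 1")
    n_runs = len(seq) // t_seq
    out = []
    for r in range(n_runs):
        sl = slice(r * t_seq, (r + 1) * t_seq)
        prov = {**seq.provenance, "run": r}
        if isinstance(seq, HybridSample):
            out.append(RPSample(x=(seq.eeg[sl], seq.fnirs[sl]), label=seq.label, provenance=prov))
        else:
            out.append(RPSample(x=seq.images[sl], label=seq.label, provenance=prov))
    return out
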