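"""End-to-end orchestration: simulate → preprocess → RP → samples → CV.

``desk_scale_experiment`` runs the whole pipeline at a size a single CPU
handles in minutes: one session per subject, a strong task effect, and RP
strides chosen so both modalities produce 50 x 50 images.  The full-scale
defaults (3 sessions, stride 10 → 100 x 100 EEG images) remain available
through the individual functions and the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import CLASS_LABELS, ChannelInfo, EventSchedule, Recording
from .evaluate import EvalReport, kfold_cv
from .model import ArchitectureSpec, TrainConfig
from .preprocess import (
    HemoRecording,
    bandpass_zero_phase,
    label_segments,
    lowpass_zero_phase,
    mbll_convert,
    resample,
)
from .recurrence import (
    EmbeddingConfig,
    RPConfig,
    RPSample,
    chunk_sequences,
    pair_hybrid,
    window_rp_sequence,
)
from .synthgen import ProtocolSpec, SubjectProfile, simulate_subject

__all__ = [
    "PipelineConfig",
    "preprocess_eeg",
    "preprocess_fnirs",
    "make_samples",
    "subject_samples",
    "run_modalities",
    "desk_scale_experiment",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything downstream of the raw recordings."""

    eeg_target_rate: float = 200.0
    eeg_band: tuple[float, float] = (1.0, 40.0)
    fnirs_target_rate: float = 10.0
    fnirs_lowpass: float = 0.2
    filter_order: int = 6
    embedding: EmbeddingConfig = EmbeddingConfig()
    # EEG images: grayscale distance maps (stride 10 at 200 Hz -> 100 x 100);
    # fNIRS images: binary plots at the absolute threshold eps = 0.1, whose
    # recurrence density encodes hemodynamic amplitude (-> 50 x 50 at 10 Hz)
    rp_eeg: RPConfig = RPConfig(step=10, output_mode="grayscale")
    rp_fnirs: RPConfig = RPConfig(
        step=1, epsilon=0.1, epsilon_mode="absolute", channel_normalize=False
    )
    t_seq: int = 4


def preprocess_eeg(rec: Recording, cfg: PipelineConfig = PipelineConfig()) -> Recording:
    """Downsample EEG to the target rate, then zero-phase bandpass it."""
    out = resample(rec, cfg.eeg_target_rate)
    return bandpass_zero_phase(out, *cfg.eeg_band, order=cfg.filter_order)


def preprocess_fnirs(
    od: Recording, cfg: PipelineConfig = PipelineConfig()
) -> HemoRecording:
    """OD → Beer–Lambert ΔHbO/ΔHbR → downsample → zero-phase low-pass."""
    hemo = mbll_convert(od)
    carrier = Recording(
        data=hemo.stacked(),
        rate=hemo.rate,
        channels=[
            ChannelInfo(label=f"{l}_{kind}", role="sd_pair")
            for kind in ("HbO", "HbR")
            for l in hemo.site_labels
        ],
        modality="fnirs_hb",
    )
    carrier = resample(carrier, cfg.fnirs_target_rate)
    carrier = lowpass_zero_phase(carrier, cfg.fnirs_lowpass, order=cfg.filter_order)
    n = len(hemo.site_labels)
    return HemoRecording(
        hbo=carrier.data[:n],
        hbr=carrier.data[n:],
        rate=carrier.rate,
        site_labels=hemo.site_labels,
    )


def make_samples(
    eeg: Recording,
    hemo: HemoRecording,
    schedules: list[EventSchedule],
    cfg: PipelineConfig = PipelineConfig(),
) -> dict[str, list[RPSample]]:
    """Labeled RP sequence samples for EEG, fNIRS and the hybrid pairing.

    Both modalities share the labeled segment boundaries in seconds, so
    their window grids align positionally even though the image sizes
    differ.
    """
    segments = label_segments(schedules)
    hemo_rec = Recording(
        data=hemo.stacked(),
        rate=hemo.rate,
        channels=[
            ChannelInfo(label=f"{l}_{kind}", role="sd_pair")
            for kind in ("HbO", "HbR")
            for l in hemo.site_labels
        ],
        modality="fnirs_hb",
    )
    out: dict[str, list[RPSample]] = {"eeg": [], "fnirs": [], "hybrid": []}
    for seg in segments.segments:
        prov = {"session": seg.session_id, "series": seg.series_id, "start": seg.start}
        eeg_seq = window_rp_sequence(
            eeg, seg.label, cfg.embedding, cfg.rp_eeg,
            start_s=seg.start, end_s=seg.end, provenance=prov,
        )
        fnirs_seq = window_rp_sequence(
            hemo_rec, seg.label, cfg.embedding, cfg.rp_fnirs,
            start_s=seg.start, end_s=seg.end, provenance=prov,
        )
        out["eeg"] += chunk_sequences(eeg_seq, cfg.t_seq)
        out["fnirs"] += chunk_sequences(fnirs_seq, cfg.t_seq)
        out["hybrid"] += chunk_sequences(pair_hybrid(eeg_seq, fnirs_seq), cfg.t_seq)
    return out


def subject_samples(
    protocol: ProtocolSpec | None = None,
    profile: SubjectProfile | None = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> dict[str, list[RPSample]]:
    """Simulate one subject and run it through the full pipeline."""
    schedules, eeg_raw, od, _, _ = simulate_subject(protocol, profile)
    eeg = preprocess_eeg(eeg_raw, cfg)
    hemo = preprocess_fnirs(od, cfg)
    return make_samples(eeg, hemo, schedules, cfg)


def run_modalities(
    samples: dict[str, list[RPSample]],
    k: int = 10,
    seed: int = 0,
    spec: ArchitectureSpec | None = None,
    cfg: TrainConfig | None = None,
    modalities=("eeg", "fnirs", "hybrid"),
) -> dict[str, EvalReport]:
    """Cross-validate each modality's classifier on the same sample split
    structure."""
    base = spec or ArchitectureSpec()
    out = {}
    for mod in modalities:
        mspec = replace(base, hybrid=(mod == "hybrid"))
        out[mod] = kfold_cv(
            samples[mod], k=k, seed=seed, spec=mspec, cfg=cfg, modality=mod
        )
    return out


#: Desk-scale study conditions: one session, pronounced workload effect,
#: 50 x 50 RPs for both modalities (EEG stride 20 at 200 Hz), short training.
DESK_PROTOCOL = ProtocolSpec(n_sessions=1)
DESK_PIPELINE = PipelineConfig(rp_eeg=RPConfig(step=20, output_mode="grayscale"), t_seq=2)
DESK_TRAIN = TrainConfig(lr=1e-3, epochs=20, batch_size=8, patience=0)
DESK_EFFECT_SIZE = 3.0
DESK_K = 5


def desk_scale_experiment(
    seed: int,
    modalities=("eeg", "fnirs", "hybrid"),
    k: int = DESK_K,
    train_cfg: TrainConfig | None = None,
) -> dict[str, EvalReport]:
    """One synthetic subject, 5-fold CV per modality, at desk scale."""
    profile = SubjectProfile(seed=seed, effect_size=DESK_EFFECT_SIZE)
    samples = subject_samples(DESK_PROTOCOL, profile, DESK_PIPELINE)
    cfg = train_cfg or replace(DESK_TRAIN, seed=seed)
    return run_modalities(samples, k=k, seed=seed, cfg=cfg, modalities=modalities)
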