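# neurorp

Recurrence-plot hybrid EEG-fNIRS mental-workload classification with a
time-distributed CNN-LSTM.

## The problem

Hybrid brain–computer interfaces record EEG (fast, 1,000 Hz, 30 channels)
and fNIRS (slow, 10.4 Hz, 16 optode sites) simultaneously, but the two
streams are hard to fuse: the usual fix — downsampling EEG to the fNIRS
rate — throws away most of the electrophysiological signal.  `neurorp`
implements an alternative: each modality's labeled signal windows are
turned into **recurrence plots** (RPs) at the modality's own sampling rate,
and the chronological RP image sequences are classified with a
**time-distributed CNN-LSTM**.  The target task is four-class n-back mental
workload (0-back, 2-back, 3-back, rest).

A recurrence plot marks every pair of times at which a system's phase-space
trajectory returns within a radius ε of itself.  After delay embedding
x_i = (x_i, x_{i+d}, …, x_{i+(m−1)d}),

    R(i, j) = 1   if ‖x(i) − x(j)‖ ≤ ε,   else 0,

computed over 5 s windows with 20 % overlap (within-window stride 10 for
EEG).  A shared convolutional block (two 3×3 convolutions, 16 filters,
ReLU, 2×2 max-pool, flatten, dense) is applied to every window in a
sequence — time-distributed, same weights per slice — followed by an LSTM
and a 4-way softmax.  The hybrid network runs one convolutional branch per
modality and concatenates the per-window features before the LSTM, so the
100×100 EEG images and 50×50 fNIRS images fuse without resampling either
signal.

The package ships a deterministic synthetic-data generator that emulates
the full experimental protocol (three sessions; 62 s series of
2 s instruction + 40 s task of twenty 2 s stimuli + 20 s rest; 180 trials
per condition) with class-dependent physiology: frontal theta up / parietal
alpha down with load in EEG, and load-scaled hemodynamic responses via the
forward modified Beer–Lambert law in fNIRS.  Real recordings are supported
through EDF (EEG), SNIRF (fNIRS) and delimited event tables.

## Worked example

```python
from neurorp.pipeline import desk_scale_experiment

reports = desk_scale_experiment(seed=1)
for modality, rep in reports.items():
    print(f"{modality:7s} accuracy {rep.accuracy:5.1f} %  f1 {rep.mean['f1']:5.1f} %")
```

This simulates one subject (one session, pronounced workload effect),
builds the RP sequences, and cross-validates the EEG-only, fNIRS-only and
hybrid classifiers (5-fold, 20 epochs).  It prints:

```
eeg     accuracy  90.7 %  f1  88.3 %
fnirs   accuracy  86.7 %  f1  88.5 %
hybrid  accuracy 100.0 %  f1 100.0 %
```

Accuracy is the fraction of held-out RP sequences classified correctly,
averaged over folds; the hybrid model matching or beating the better single
modality is the central qualitative claim of the approach.  (Stochastic
training on 54 samples: expect several points of movement across seeds.)

The same experiment is available from a shell:

```bash
neurorp simulate --subjects 1 --seed 0 --out data/      # EDF + SNIRF + events
neurorp run-all --seed 1 --out results/                 # simulate → RP → CV
```

## Layout

- `src/neurorp/core_io.py` — data model; EDF/SNIRF/events/container I/O
- `src/neurorp/synthgen.py` — protocol schedules and synthetic EEG/fNIRS
- `src/neurorp/preprocess.py` — resampling, zero-phase Butterworth filters,
  modified Beer–Lambert conversion, labeling, outlier rejection,
  normalization
- `src/neurorp/recurrence.py` — delay embedding, distance matrices, RP
  thresholding, windowed RP sequences, hybrid pairing
- `src/neurorp/nn.py`, `src/neurorp/model.py` — NumPy layers and the
  time-distributed CNN-LSTM
- `src/neurorp/evaluate.py` — metrics, stratified k-fold CV, reporting
- `src/neurorp/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — models, parameters, design choices, limitations
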