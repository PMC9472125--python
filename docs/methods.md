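# Methods

## Problem and approach

`neurorp` classifies four mental-workload states (0-back, 2-back, 3-back,
rest) from simultaneous EEG and fNIRS recordings of an n-back protocol.
The central idea is to make the two modalities compatible without
downsampling either one to the other's rate: each modality's labeled signal
windows are converted into square recurrence-plot (RP) images at the
modality's own sampling rate, and the chronological image sequences are
classified with a time-distributed CNN-LSTM.  The hybrid variant fuses both
modalities by running one convolutional branch per modality and
concatenating the per-window feature vectors before the LSTM, so the
differing image sizes never have to be reconciled at the signal level.

## Experimental protocol emulated by the generator

A session holds a randomized sequence of nine series (three per n-back
condition).  A series is 2 s of instruction, a 40 s task block of twenty
2 s stimuli, and 20 s of rest — 62 s in total.  Three sessions give
3 × 3 × 20 = 180 trials per condition.  EEG is 30 channels at 1,000 Hz;
fNIRS is 16 source-detector sites, two wavelengths (760/850 nm), at
10.4 Hz.

The synthetic subject injects class structure through standard
working-memory physiology:

* **EEG** — frontal-midline theta (6 Hz) amplitude scales as
  `1 + load × effect_size` and parietal alpha (9.5 Hz) as its reciprocal,
  with load factors 0.5 / 1.0 / 1.5 for 0-/2-/3-back.  Pink (1/f)
  background (8 µV), 50 Hz mains (1 µV) and linear drift are superimposed.
* **fNIRS** — each task block drives a boxcar convolved with a canonical
  double-gamma hemodynamic response (peak ≈ 6 s, undershoot ≈ 16 s).  The
  plateau amplitude is 0.4 µmol/L per unit `load × effect_size`, keeping
  ΔHbO in the physiologic sub-2-µmol/L range; ΔHbR = −ΔHbO/3.  The neural
  drive carries slow (< 0.3 Hz) multiplicative variability (sd 0.6 × drive)
  so that windows inside the plateau remain load-dependent — without it,
  every sustained block looks identical once an RP normalizes scale.
  Mayer waves (0.1 Hz, 0.08 µmol/L), respiration (0.25 Hz, 0.05),
  cardiac (1.1 Hz, 0.03) and white sensor noise (0.02) are added, and
  optical densities are produced by the forward modified Beer–Lambert law
  (DPF 6.0, source-detector distance 3 cm, compiled in-vitro hemoglobin
  extinction spectra).

Everything is deterministic given the subject seed.  What the generator
does **not** model: volume conduction and realistic EEG topography, motion
artifacts, optode coupling changes, inter-subject anatomical variability,
and the initial dip of the hemodynamic response.  Passing tests therefore
demonstrate that the pipeline recovers class structure of the kind the
generator encodes, not that any particular accuracy transfers to real
recordings.

## Pre-processing

* EEG: polyphase resampling 1,000 → 200 Hz (Kaiser-windowed FIR
  anti-aliasing), then a zero-phase 6th-order Butterworth bandpass
  1–40 Hz.
* fNIRS: optical density → ΔHbO/ΔHbR via the modified Beer–Lambert
  inverse per site, resampling 10.4 → 10 Hz (rational factor 25/26), then
  a zero-phase 6th-order Butterworth low-pass at 0.2 Hz.

Zero phase is realized by forward-backward SOS filtering with odd
reflective padding; two passes square the magnitude response, which is what
the filter tests check against analytically.  The Beer–Lambert inverse does
not re-reference OD to its temporal mean: amplitude-derived OD is already
mean-referenced when read from file, and re-referencing inside the inverse
would shift the recovered concentrations by a constant (breaking the exact
forward/inverse round trip the tests enforce).  A `baseline="mean"` option
restores that behavior when inputs are raw.

Outlier rejection (robust per-channel z-score over windows, default
`z_max = 5`) and training-fold z-scoring are available as explicit,
leakage-safe steps; the RP representations used by the classifier are
already bounded in [0, 1], so the cross-validation path does not re-scale
them.

## Recurrence plots

Windows of 5 s with 20 % overlap are cut from each labeled segment
(instruction periods are excluded; a 40 s task block yields 9 windows, a
20 s rest 4).  Within a window, samples are strided (default step 10 for
EEG → 100-point windows at 200 Hz; step 1 for fNIRS → 50 points at 10 Hz),
all channels are stacked into one state vector per time point (delay
embedding with m = 1, d = 1 by default; m ≥ 2n+1 is checked and warned
about when a system dimension is declared), and the pairwise Euclidean
distance matrix is thresholded:

    R(i, j) = 1  if ||x(i) − x(j)|| ≤ ε  else 0.

Two threshold interpretations are supported: a fraction of the window's
maximum distance (default 0.1; scale-free) and the literal absolute value.
A grayscale mode returns the distance map `1 − D/max(D)` instead of
thresholding.

**Classifier inputs.**  The defaults feed the network different RP styles
per modality, for reasons that follow from the geometry of the data:

* With 30 stacked EEG channels, pairwise distances concentrate sharply
  (high-dimensional measure concentration), so a binary plot at 0.1 × max
  retains ~2 % density and almost no texture.  The EEG branch therefore
  uses the grayscale distance map, which preserves the full distance
  geometry of the window.
* For fNIRS, workload is amplitude-coded (higher load → larger ΔHbO), and
  any scale-normalized image erases exactly that.  The fNIRS branch uses
  the binary plot at the absolute threshold ε = 0.1 (µmol/L scale): its
  recurrence density then decreases monotonically with hemodynamic
  amplitude and becomes the discriminant the network reads.

Consecutive non-overlapping runs of `t_seq` windows (default 4) sharing a
label form one classifier sample, so overlapping windows can never straddle
a fold boundary.

## Network and training

Per time step (window), a shared convolutional block — two 3×3
convolutions with 16 filters and ReLU, one 2×2 max-pool, flatten, and a
64-unit dense projection — is applied time-distributed.  The per-window
features (concatenated across branches for the hybrid model) feed a
64-unit LSTM; its final state passes through a 32-unit dense layer into a
4-way softmax.  Training uses Adam (lr 1e-3), categorical cross-entropy,
batch size 32, up to 50 epochs with optional early stopping on validation
loss (patience 10).  These hyperparameters are package defaults exposed in
configuration; they were fixed by design rather than searched.

The engine is a small NumPy implementation (im2col convolutions, exact
max-pool tie handling, BPTT through the LSTM) and is float32 and
deterministic given the seeds; its gradients are verified against finite
differences in the test suite.

## Evaluation

Accuracy is the fraction of correct predictions; precision and recall are
one-vs-rest per class, macro-averaged over the fixed class order; F1 is the
harmonic mean of the macro precision and macro recall; all are reported in
percent.  Cross-validation is stratified k-fold (default k = 10) over
classifier samples with per-fold training from scratch; fold assignment,
initialization and shuffling all derive from the experiment seed.

## Desk-scale experiment

`pipeline.desk_scale_experiment` fixes study conditions a single CPU
handles in minutes: one session per subject, `effect_size = 3.0`
(pronounced workload contrast), EEG stride 20 (50 × 50 images), sequence
length `t_seq = 2` (54 samples per subject, which keeps 5-fold test folds
large enough that one sample moves a fold's accuracy by ~9 rather than
~17 points), 5-fold CV, and 20 epochs of Adam at lr 1e-3 with batch 8.
The acceptance script reports the cross-validated accuracy of the EEG,
fNIRS and hybrid classifiers under these conditions.

## Known limitations

* The multichannel RP (stacked channels) is one of several reasonable
  readings of applying the RP construction to multichannel data;
  per-channel plots would need a different network head.
* The hybrid fusion is plain per-window feature concatenation; when one
  modality is much more informative than the other, the fused model can
  trail the better single modality by a small margin at small sample
  sizes.
* fNIRS class information in the generator is amplitude- plus
  variability-coded; discriminants that real cortical hemodynamics may
  offer (spatial patterns, latency shifts) are not modeled.
* No motion-artifact correction or ICA denoising is included.
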