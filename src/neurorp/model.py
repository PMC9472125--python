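"""Time-distributed CNN-LSTM classifier over RP image sequences.

Each input sample is a chronological sequence of T_seq square RP images
(one per 5 s window).  A convolutional block — two 3x3 convolutions with 16
filters and ReLU, a 2x2 max-pool, a flatten and a dense projection — is
wrapped time-distributed: the same weights are applied to every temporal
slice.  The per-window feature vectors feed an LSTM whose final state
passes through a dense layer into a 4-way softmax (0-back, 2-back, 3-back,
rest).  The hybrid variant runs one convolutional branch per modality and
concatenates the branch features per time step before the LSTM, so EEG and
fNIRS images of different sizes can be fused without resampling either
modality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import CLASS_LABELS
from . import nn
from .recurrence import RPSample

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "TDCNNLSTM",
    "TrainedClassifier",
    "build_model",
    "train",
    "predict_proba",
    "samples_to_arrays",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the network; defaults mirror the reference design."""

    conv_filters: int = 16
    kernel: int = 3
    td_dense_units: int = 64
    lstm_units: int = 64
    head_dense_units: int = 32
    n_classes: int = 4
    hybrid: bool = False

    def __post_init__(self) -> None:
        for name in ("conv_filters", "td_dense_units", "lstm_units",
                     "head_dense_units", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    patience: int = 10  # early stopping on validation loss; 0 disables

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _conv_branch(spec: ArchitectureSpec, hw: int, rng) -> nn.Sequential:
    f = spec.conv_filters
    flat = (hw // 2) * (hw // 2) * f
    return nn.Sequential([
        nn.Conv2D(1, f, spec.kernel, rng),
        nn.ReLU(),
        nn.Conv2D(f, f, spec.kernel, rng),
        nn.ReLU(),
        nn.MaxPool2(),
        nn.Flatten(),
        nn.Dense(flat, spec.td_dense_units, rng),
        nn.ReLU(),
    ])


class TDCNNLSTM:
    """The assembled network; one conv branch per modality, shared over time."""

    def __init__(self, spec: ArchitectureSpec, input_shapes, seed: int = 0):
        if isinstance(input_shapes, tuple) and np.isscalar(input_shapes[0]):
            input_shapes = [input_shapes]
        input_shapes = [tuple(s) for s in input_shapes]
        if spec.hybrid and len(input_shapes) != 2:
            raise ValueError("hybrid model needs two input shapes (EEG, fNIRS)")
        if not spec.hybrid and len(input_shapes) != 1:
            raise ValueError("single-modality model takes exactly one input shape")
        for s in input_shapes:
            if len(s) not in (3, 4) or s[1] != s[2]:
                raise ValueError(f"input shape {s} is not (T_seq, H, H[, 1]) with square RPs")
        input_shapes = [s[:3] for s in input_shapes]  # canonical (T_seq, H, W)
        self.spec = spec
        self.input_shapes = input_shapes
        self.t_seq = input_shapes[0][0]
        rng = np.random.default_rng(seed)
        self.branches = [_conv_branch(spec, s[1], rng) for s in input_shapes]
        feat = spec.td_dense_units * len(self.branches)
        self.lstm = nn.LSTM(feat, spec.lstm_units, rng)
        self.head = nn.Sequential([
            nn.Dense(spec.lstm_units, spec.head_dense_units, rng),
            nn.ReLU(),
            nn.Dense(spec.head_dense_units, spec.n_classes, rng),
        ])

    def params(self):
        out = []
        for b in self.branches:
            out += b.params()
        out += self.lstm.params()
        out += self.head.params()
        return out

    def zero_grad(self) -> None:
        for _, _, g in self.params():
            g[...] = 0

    @property
    def n_params(self) -> int:
        return int(sum(v.size for _, v, _ in self.params()))

    def _check(self, xs) -> list[np.ndarray]:
        if not isinstance(xs, (list, tuple)):
            xs = [xs]
        if len(xs) != len(self.branches):
            raise ValueError(
                f"model expects {len(self.branches)} input stream(s), got {len(xs)}"
            )
        out = []
        for x, want in zip(xs, self.input_shapes):
            x = np.asarray(x, dtype=nn.F32)
            if x.ndim == 3 and x.shape == want:
                x = x[None]  # single sample, no channel axis
            elif x.ndim == 4 and tuple(x.shape[:3]) == want and x.shape[3] == 1:
                x = x[None]  # single sample with channel axis
            if not (
                x.ndim in (4, 5)
                and tuple(x.shape[1:4]) == want
                and (x.ndim == 4 or x.shape[4] == 1)
            ):
                raise ValueError(
                    f"expected input shape (N, {want[0]}, {want[1]}, {want[2]}[, 1]), "
                    f"got {tuple(x.shape)}"
                )
            if x.ndim == 4:
                x = x[..., None]
            out.append(x)
        return out

    def forward(self, xs, train: bool = True) -> np.ndarray:
        xs = self._check(xs)
        n = xs[0].shape[0]
        feats = []
        for x, branch in zip(xs, self.branches):
            t = x.shape[1]
            # time-distributed: fold time into the batch axis, shared weights
            flat = branch.forward(x.reshape(n * t, *x.shape[2:]), train=train)
            feats.append(flat.reshape(n, t, -1))
        seq = np.concatenate(feats, axis=2) if len(feats) > 1 else feats[0]
        h = self.lstm.forward(seq, train=train)
        return self.head.forward(h, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        dseq = self.lstm.backward(dh)
        offset = 0
        for branch, shape in zip(self.branches, self.input_shapes):
            width = self.spec.td_dense_units
            n, t = dseq.shape[0], dseq.shape[1]
            dpart = dseq[:, :, offset : offset + width].reshape(n * t, width)
            branch.backward(np.ascontiguousarray(dpart))
            offset += width


@dataclass
class TrainedClassifier:
    """A fitted model plus its training history and label ordering."""

    net: TDCNNLSTM
    classes: tuple[str, ...]
    history: dict = field(default_factory=dict)
    config: TrainConfig | None = None


def build_model(
    spec: ArchitectureSpec, input_shapes, seed: int = 0
) -> TDCNNLSTM:
    """Construct the untrained network for the given RP tensor shape(s).

    ``input_shapes`` is ``(T_seq, H, W[, 1])`` for a single modality or a
    list of two such shapes for the hybrid network.
    """
    return TDCNNLSTM(spec, input_shapes, seed=seed)


def samples_to_arrays(samples: list[RPSample], classes=CLASS_LABELS):
    """Stack RPSamples into network inputs and integer labels."""
    if not samples:
        raise ValueError("no samples")
    y = np.array([classes.index(s.label) for s in samples])
    if isinstance(samples[0].x, tuple):
        xs = [
            np.stack([s.x[0] for s in samples]).astype(nn.F32),
            np.stack([s.x[1] for s in samples]).astype(nn.F32),
        ]
    else:
        xs = [np.stack([s.x for s in samples]).astype(nn.F32)]
    return xs, y


def _slice_xs(xs, idx):
    return [x[idx] for x in xs]


def train(
    net: TDCNNLSTM,
    samples: list[RPSample],
    cfg: TrainConfig,
    val_samples: list[RPSample] | None = None,
    classes=CLASS_LABELS,
) -> TrainedClassifier:
    """Fit the network with Adam on categorical cross-entropy.

    Deterministic given ``cfg.seed`` (initialization is fixed by the seed
    passed to :func:`build_model`; shuffling by ``cfg.seed``).  Early
    stopping watches validation loss when validation samples are provided.
    """
    xs, y = samples_to_arrays(samples, classes)
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    val = samples_to_arrays(val_samples, classes) if val_samples else None
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(net.params(), lr=cfg.lr)
    n = y.size
    history = {"loss": [], "acc": [], "val_loss": [], "val_acc": []}
    best_val = np.inf
    best_state = None
    stall = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_hits = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            net.zero_grad()
            logits = net.forward(_slice_xs(xs, idx), train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * idx.size
            ep_hits += int((logits.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(ep_loss / n)
        history["acc"].append(ep_hits / n)
        if val is not None:
            vlogits = net.forward(val[0], train=False)
            vloss, _ = nn.softmax_cross_entropy(vlogits, val[1])
            history["val_loss"].append(vloss)
            history["val_acc"].append(float((vlogits.argmax(axis=1) == val[1]).mean()))
            if cfg.patience:
                if vloss < best_val - 1e-6:
                    best_val = vloss
                    best_state = [v.copy() for _, v, _ in net.params()]
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
    if best_state is not None:
        for (_, v, _), saved in zip(net.params(), best_state):
            v[...] = saved
    return TrainedClassifier(net=net, classes=tuple(classes), history=history, config=cfg)


def predict_proba(clf: TrainedClassifier | TDCNNLSTM, samples) -> np.ndarray:
    """Class-probability matrix (rows on the simplex, order = ``classes``)."""
    net = clf.net if isinstance(clf, TrainedClassifier) else clf
    if isinstance(samples, list) and samples and isinstance(samples[0], RPSample):
        xs, _ = samples_to_arrays(samples)
    elif isinstance(samples, (list, tuple)) and isinstance(samples[0], np.ndarray) \
            and len(samples) == len(net.branches):
        xs = list(samples)
    else:
        xs = [np.asarray(samples)]
    logits = net.forward(xs, train=False)
    return nn.softmax(logits.astype(np.float64))


def predict(clf: TrainedClassifier, samples) -> list[str]:
    proba = predict_proba(clf, samples)
    classes = clf.classes if isinstance(clf, TrainedClassifier) else CLASS_LABELS
    return [classes[i] for i in proba.argmax(axis=1)]
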