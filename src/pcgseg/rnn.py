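"""Bidirectional GRU frame classifier over the five heart-sound states.

A three-layer bidirectional GRU (hidden size 60) reads the z-scored
log-spectrogram frames; its concatenated forward/backward outputs pass
through a two-layer fully connected head (60 and 40 units, Tanh) and a
softmax over the five states (S1, systole, S2, diastole, murmur).  Dropout
with probability 0.1 sits between the recurrent stack and the head.  The
network is trained with class-frequency-weighted cross-entropy and Adam;
the recurrence lets it exploit the timing of sounds, which purely per-frame
classifiers cannot.

The network, its gradients and the optimiser are implemented directly on
numpy arrays; gradient correctness is established against finite
differences in the test suite.  All randomness (initialisation, batch
order, dropout) is driven by a single seed, so training is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .annotation import FrameLabels
from .features import SpectroFrames
from .io_formats import STATE_ORDER

N_CLASSES = len(STATE_ORDER)


@dataclass
class RnnConfig:
    input_dim: int = 41
    rnn_layers: int = 3
    hidden: int = 60
    fc_sizes: tuple = (60, 40)
    dropout: float = 0.1
    classes: int = N_CLASSES
    bidirectional: bool = True
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 16
    patience: int = 10
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        sizes = (self.input_dim, self.rnn_layers, self.hidden, self.classes,
                 *self.fc_sizes, self.batch_size, self.epochs)
        if any(s <= 0 for s in sizes):
            raise ValueError("all sizes must be positive")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def build_rnn(cfg: RnnConfig) -> "BiGruClassifier":
    """Construct a (seeded) untrained classifier for the given configuration."""
    return BiGruClassifier(cfg)


class BiGruClassifier:
    """Numpy BiGRU + FC head mapping (T, input_dim) features to (T, 5) posteriors."""

    def __init__(self, cfg: RnnConfig):
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(cfg.seed)
        H = cfg.hidden
        self.n_dir = 2 if cfg.bidirectional else 1
        in_dim = cfg.input_dim
        for layer in range(cfg.rnn_layers):
            for d in range(self.n_dir):
                k = 1.0 / np.sqrt(H)
                pre = f"gru{layer}_{d}"
                self.params[f"{pre}_W"] = rng.uniform(-k, k, (in_dim, 3 * H))
                self.params[f"{pre}_U"] = rng.uniform(-k, k, (H, 3 * H))
                self.params[f"{pre}_bi"] = rng.uniform(-k, k, 3 * H)
                self.params[f"{pre}_bh"] = rng.uniform(-k, k, 3 * H)
            in_dim = self.n_dir * H
        dims = [in_dim, *cfg.fc_sizes, cfg.classes]
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            k = 1.0 / np.sqrt(a)
            self.params[f"fc{i}_W"] = rng.uniform(-k, k, (a, b))
            self.params[f"fc{i}_b"] = rng.uniform(-k, k, b)
        self.n_fc = len(dims) - 1

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # ------------------------------------------------------------- forward

    def _gru_direction(self, X, pre):
        """One GRU direction over X (B, T, D); returns hidden states and cache.

        Gate order in the stacked weight matrices is (reset, update, new).
        """
        W, U = self.params[f"{pre}_W"], self.params[f"{pre}_U"]
        bi, bh = self.params[f"{pre}_bi"], self.params[f"{pre}_bh"]
        B, T, _ = X.shape
        H = self.cfg.hidden
        gx = X @ W + bi  # input projections for all t at once
        h = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = {"r": np.empty((B, T, H)), "z": np.empty((B, T, H)),
                 "n": np.empty((B, T, H)), "ghn": np.empty((B, T, H)),
                 "hprev": np.empty((B, T, H)), "gx": gx, "X": X}
        for t in range(T):
            gh = h @ U + bh
            r = _sigmoid(gx[:, t, :H] + gh[:, :H])
            z = _sigmoid(gx[:, t, H:2 * H] + gh[:, H:2 * H])
            ghn = gh[:, 2 * H:]
            n = np.tanh(gx[:, t, 2 * H:] + r * ghn)
            cache["hprev"][:, t] = h
            h = (1.0 - z) * n + z * h
            hs[:, t] = h
            cache["r"][:, t], cache["z"][:, t] = r, z
            cache["n"][:, t], cache["ghn"][:, t] = n, ghn
        return hs, cache

    def forward(self, X, train: bool = False,
                rng: np.random.Generator | None = None):
        """X: (B, T, input_dim) -> probs (B, T, classes), plus backprop cache."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[-1] != self.cfg.input_dim:
            raise ValueError(
                f"expected {self.cfg.input_dim} feature columns, got {X.shape[-1]}")
        gru_caches = []
        out = X
        for layer in range(self.cfg.rnn_layers):
            outs, layer_caches = [], []
            for d in range(self.n_dir):
                inp = out if d == 0 else out[:, ::-1]
                hs, c = self._gru_direction(np.ascontiguousarray(inp),
                                            f"gru{layer}_{d}")
                outs.append(hs if d == 0 else hs[:, ::-1])
                layer_caches.append(c)
            out = np.concatenate(outs, axis=2)
            gru_caches.append(layer_caches)
        drop_mask = None
        if train and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            drop_mask = (rng.random(out.shape) < keep) / keep
            out = out * drop_mask
        fc_inputs = []  # input array of each FC layer
        a = out
        for i in range(self.n_fc):
            fc_inputs.append(a)
            zlin = a @ self.params[f"fc{i}_W"] + self.params[f"fc{i}_b"]
            a = np.tanh(zlin) if i < self.n_fc - 1 else zlin
        m = a.max(axis=-1, keepdims=True)
        e = np.exp(a - m)
        probs = e / e.sum(axis=-1, keepdims=True)
        cache = {"gru": gru_caches, "drop_mask": drop_mask,
                 "fc_inputs": fc_inputs, "probs": probs}
        return probs, cache

    # ------------------------------------------------------------ backward

    def _gru_direction_backward(self, dhs, pre, cache, grads):
        W, U = self.params[f"{pre}_W"], self.params[f"{pre}_U"]
        B, T, H = dhs.shape
        gx, X = cache["gx"], cache["X"]
        dgx = np.zeros_like(gx)
        dU = np.zeros_like(U)
        dbh = np.zeros(3 * H)
        dh = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            dh = dh + dhs[:, t]
            r, z = cache["r"][:, t], cache["z"][:, t]
            n, ghn = cache["n"][:, t], cache["ghn"][:, t]
            hprev = cache["hprev"][:, t]
            dn = dh * (1.0 - z)
            dz = dh * (hprev - n)
            dh_prev = dh * z
            da_n = dn * (1.0 - n * n)
            dr = da_n * ghn
            dghn = da_n * r
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            dgx[:, t, :H] = da_r
            dgx[:, t, H:2 * H] = da_z
            dgx[:, t, 2 * H:] = da_n
            dgh = np.concatenate([da_r, da_z, dghn], axis=1)
            dU += hprev.T @ dgh
            dbh += dgh.sum(axis=0)
            dh = dh_prev + dgh @ U.T
        flatX = X.reshape(-1, X.shape[-1])
        flatdgx = dgx.reshape(-1, 3 * H)
        grads[f"{pre}_W"] += flatX.T @ flatdgx
        grads[f"{pre}_bi"] += flatdgx.sum(axis=0)
        grads[f"{pre}_U"] += dU
        grads[f"{pre}_bh"] += dbh
        return dgx @ W.T

    def backward(self, cache, dlogits):
        """Parameter gradients given d(loss)/d(logits)."""
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dz = dlogits
        for i in range(self.n_fc - 1, -1, -1):
            a_in = cache["fc_inputs"][i]
            flat_in = a_in.reshape(-1, a_in.shape[-1])
            flat_dz = dz.reshape(-1, dz.shape[-1])
            grads[f"fc{i}_W"] += flat_in.T @ flat_dz
            grads[f"fc{i}_b"] += flat_dz.sum(axis=0)
            da_in = dz @ self.params[f"fc{i}_W"].T
            if i > 0:
                # a_in is the tanh output of the previous linear layer
                dz = da_in * (1.0 - a_in**2)
            else:
                dz = da_in
        dout = dz
        if cache["drop_mask"] is not None:
            dout = dout * cache["drop_mask"]
        H = self.cfg.hidden
        for layer in range(self.cfg.rnn_layers - 1, -1, -1):
            layer_caches = cache["gru"][layer]
            dX_total = None
            for d in range(self.n_dir):
                dhs = dout[:, :, d * H:(d + 1) * H]
                if d == 1:
                    dhs = dhs[:, ::-1]
                dX = self._gru_direction_backward(
                    np.ascontiguousarray(dhs), f"gru{layer}_{d}",
                    layer_caches[d], grads)
                if d == 1:
                    dX = dX[:, ::-1]
                dX_total = dX if dX_total is None else dX_total + dX
            dout = dX_total
        return grads

    # ----------------------------------------------------------- inference

    def predict_posteriors(self, sf: SpectroFrames) -> np.ndarray:
        """T x 5 row-stochastic posterior matrix (dropout disabled)."""
        probs, _ = self.forward(sf.values[None, :, :], train=False)
        return probs[0]

    # --------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Self-describing checkpoint: config JSON + weights (npz)."""
        path = Path(path)
        cfg = asdict(self.cfg)
        cfg["fc_sizes"] = list(cfg["fc_sizes"])
        np.savez(path, __config__=json.dumps(cfg), **self.params)

    @classmethod
    def load(cls, path) -> "BiGruClassifier":
        data = np.load(Path(path), allow_pickle=False)
        cfg_dict = json.loads(str(data["__config__"]))
        cfg_dict["fc_sizes"] = tuple(cfg_dict["fc_sizes"])
        model = cls(RnnConfig(**cfg_dict))
        for k in model.params:
            model.params[k] = data[k]
        return model


# ---------------------------------------------------------------- training


def class_weights(label_sets: list[FrameLabels]) -> np.ndarray:
    """Inverse-frequency class weights, rescaled to mean 1.

    Raises ``ValueError`` naming any state that never occurs, since its
    weight would be infinite.
    """
    counts = np.zeros(N_CLASSES)
    for fl in label_sets:
        counts += np.bincount(fl.states, minlength=N_CLASSES)
    missing = [STATE_ORDER[i] for i in range(N_CLASSES) if counts[i] == 0]
    if missing:
        raise ValueError(f"no training frames for state(s): {', '.join(missing)}")
    w = 1.0 / counts
    return w / w.mean()


def weighted_cross_entropy(probs, labels, weights):
    """Mean weighted negative log-likelihood and the logit gradient."""
    B, T, C = probs.shape
    flat_p = probs.reshape(-1, C)
    flat_y = labels.reshape(-1)
    w = weights[flat_y]
    nll = -np.log(np.maximum(flat_p[np.arange(len(flat_y)), flat_y], 1e-30))
    loss = float((w * nll).mean())
    dlogits = flat_p * w[:, None]
    dlogits[np.arange(len(flat_y)), flat_y] -= w
    dlogits /= len(flat_y)
    return loss, dlogits.reshape(B, T, C)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def _batches_by_length(indices, lengths, batch_size):
    """Group recording indices of equal frame count into batches (no padding)."""
    by_len: dict[int, list[int]] = {}
    for i in indices:
        by_len.setdefault(lengths[i], []).append(i)
    batches = []
    for _, idxs in sorted(by_len.items()):
        for j in range(0, len(idxs), batch_size):
            batches.append(idxs[j:j + batch_size])
    return batches


def frame_accuracy(model: BiGruClassifier,
                   dataset: list[tuple[SpectroFrames, FrameLabels]]) -> float:
    """Fraction of frames whose argmax posterior matches the ground truth."""
    correct = total = 0
    for sf, fl in dataset:
        pred = np.argmax(model.predict_posteriors(sf), axis=1)
        correct += int((pred == fl.states).sum())
        total += len(fl)
    return correct / total


def train_rnn(
    model: BiGruClassifier,
    dataset: list[tuple[SpectroFrames, FrameLabels]],
    cfg: RnnConfig | None = None,
    log: list | None = None,
) -> BiGruClassifier:
    """Train with weighted cross-entropy + Adam; keep the best-validation weights.

    Recordings are grouped by frame count so batches need no padding (padding
    frames would distort the class weights).  A ``val_fraction`` split of
    recordings is held out for early stopping with the configured patience;
    with fewer than 5 recordings everything is used for training and the
    final weights are returned.  ``log`` (if given) collects per-epoch dicts
    of losses and training frame accuracy.
    """
    cfg = cfg or model.cfg
    if not dataset:
        raise ValueError("empty training dataset")
    for sf, fl in dataset:
        if sf.n_frames != len(fl):
            raise ValueError("feature/label length mismatch")
    rng = np.random.default_rng(cfg.seed + 1)
    weights = class_weights([fl for _, fl in dataset])

    n = len(dataset)
    perm = rng.permutation(n)
    n_val = int(round(cfg.val_fraction * n)) if n >= 5 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    lengths = [sf.n_frames for sf, _ in dataset]

    opt = _Adam(model.params, cfg.learning_rate)
    best_val = np.inf
    best_params = None
    stale = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        batches = _batches_by_length(order.tolist(), lengths, cfg.batch_size)
        rng.shuffle(batches)
        epoch_loss = 0.0
        n_frames_seen = 0
        for batch in batches:
            X = np.stack([dataset[i][0].values for i in batch])
            Y = np.stack([dataset[i][1].states for i in batch])
            probs, cache = model.forward(X, train=True, rng=rng)
            loss, dlogits = weighted_cross_entropy(probs, Y, weights)
            grads = model.backward(cache, dlogits)
            opt.step(model.params, grads)
            epoch_loss += loss * Y.size
            n_frames_seen += Y.size
        train_loss = epoch_loss / max(n_frames_seen, 1)

        if n_val:
            val_loss = 0.0
            val_frames = 0
            for i in val_idx:
                sf, fl = dataset[i]
                probs, _ = model.forward(sf.values[None], train=False)
                loss, _ = weighted_cross_entropy(probs, fl.states[None], weights)
                val_loss += loss * len(fl)
                val_frames += len(fl)
            val_loss /= val_frames
        else:
            val_loss = train_loss
        if log is not None:
            log.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best_params is not None:
        model.params = best_params
    return model


def predict_posteriors(model: BiGruClassifier, sf: SpectroFrames) -> np.ndarray:
    """Functional alias for :meth:`BiGruClassifier.predict_posteriors`."""
    return model.predict_posteriors(sf)
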