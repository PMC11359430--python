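"""BiLSTM classifier for feature matrices, implemented in NumPy.

Architecture (binary AF/NSR classification): the per-record feature matrix
(frames x [bands + time-domain features]) is standardized with statistics
from the training set and passed through a ReLU, then a single
bidirectional LSTM layer; the concatenated final hidden states of the
forward and backward passes feed a fully-connected ReLU layer and a 2-unit
SoftMax output.  Label order is [NSR=0, AF=1].

Training uses Adam with a stepwise learning-rate schedule
``lr(e) = initial_lr * lrdf ** floor(e / decay_period_epochs)`` and is
deterministic given the config seed.  Gradients are exact analytic BPTT
(verified against finite differences in the test suite).

The learning-rate range test sweeps a geometric lr grid, taking one
optimizer step per batch and retaining each batch loss; the suggested
initial lr is the minimizer of the 5-point-smoothed loss curve (its
descending branch), computed on the finite prefix if the loss diverges.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .features import FeatureMatrix

LABEL_ORDER = ("NSR", "AF")  # NSR=0, AF=1


@dataclass(frozen=True)
class NetConfig:
    hidden_units_per_direction: int = 64
    n_layers: int = 1
    fc_units: int = 32
    initial_lr: float = 0.01525
    lrdf: float = 0.5
    decay_period_epochs: int = 10
    max_epochs: int = 100
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lrdf <= 1):
            raise ValueError("lrdf must lie in (0, 1]")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.n_layers != 1:
            raise ValueError("only a single BiLSTM layer is supported")
        if self.hidden_units_per_direction < 1 or self.fc_units < 1:
            raise ValueError("layer widths must be >= 1")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class BiLSTMClassifier:
    """Weights, input-normalization statistics and training history."""

    def __init__(self, cfg: NetConfig, input_dim: int):
        self.cfg = cfg
        self.input_dim = input_dim
        H, F = cfg.hidden_units_per_direction, cfg.fc_units
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}
        for d in ("fwd", "bwd"):
            self.params[f"W_{d}"] = _glorot(rng, input_dim, 4 * H)
            self.params[f"U_{d}"] = _glorot(rng, H, 4 * H)
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"b_{d}"] = b
        self.params["W_fc"] = _glorot(rng, 2 * H, F)
        self.params["b_fc"] = np.zeros(F)
        self.params["W_out"] = _glorot(rng, F, 2)
        self.params["b_out"] = np.zeros(2)
        # input standardization (identity until fitted on a training set)
        self.norm_mean = np.zeros(input_dim)
        self.norm_sd = np.ones(input_dim)
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": [], "lr": []}
        self.trained = False
        # Adam state
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- assembly ----------------------------------------------------------

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def clone(self) -> "BiLSTMClassifier":
        return copy.deepcopy(self)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        """Standardize per feature, then ReLU (the input activation)."""
        Z = (X - self.norm_mean) / self.norm_sd
        return np.maximum(Z, 0.0)

    # -- forward / backward ------------------------------------------------

    def _lstm_forward(self, X: np.ndarray, direction: str):
        """X: (B, T, D) in processing order.  Returns last hidden state and
        the per-step cache needed for BPTT."""
        H = self.cfg.hidden_units_per_direction
        W = self.params[f"W_{direction}"]
        U = self.params[f"U_{direction}"]
        b = self.params[f"b_{direction}"]
        B, T, _ = X.shape
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            x_t = X[:, t, :]
            z = x_t @ W + h @ U + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x_t, h, c, i, f, g, o, c_new, tc))
            h, c = h_new, c_new
        return h, cache

    def _lstm_backward(self, dh_last: np.ndarray, cache, direction: str, grads):
        H = self.cfg.hidden_units_per_direction
        U = self.params[f"U_{direction}"]
        dW = grads[f"W_{direction}"]
        dU = grads[f"U_{direction}"]
        db = grads[f"b_{direction}"]
        dh = dh_last
        dc = np.zeros_like(dh_last)
        for x_t, h_prev, c_prev, i, f, g, o, c_new, tc in reversed(cache):
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dW += x_t.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dh = dz @ U.T
            dc = dc * f

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch X of shape (B, T, D)."""
        probs, _ = self._forward_full(self._transform(X))
        return probs

    def _forward_full(self, A: np.ndarray):
        h_fwd, cache_f = self._lstm_forward(A, "fwd")
        h_bwd, cache_b = self._lstm_forward(A[:, ::-1, :], "bwd")
        hcat = np.concatenate([h_fwd, h_bwd], axis=1)
        a1 = np.maximum(hcat @ self.params["W_fc"] + self.params["b_fc"], 0.0)
        logits = a1 @ self.params["W_out"] + self.params["b_out"]
        probs = _softmax(logits)
        return probs, (A, cache_f, cache_b, hcat, a1)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and analytic gradients for raw features X."""
        A = self._transform(X)
        probs, (A, cache_f, cache_b, hcat, a1) = self._forward_full(A)
        B = X.shape[0]
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads["W_out"] += a1.T @ dlogits
        grads["b_out"] += dlogits.sum(axis=0)
        da1 = dlogits @ self.params["W_out"].T
        dz1 = da1 * (a1 > 0)
        grads["W_fc"] += hcat.T @ dz1
        grads["b_fc"] += dz1.sum(axis=0)
        dhcat = dz1 @ self.params["W_fc"].T
        H = self.cfg.hidden_units_per_direction
        self._lstm_backward(dhcat[:, :H], cache_f, "fwd", grads)
        self._lstm_backward(dhcat[:, H:], cache_b, "bwd", grads)
        return loss, grads

    # -- optimization ------------------------------------------------------

    def _adam_step(self, grads: dict[str, np.ndarray], lr: float,
                   beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        meta = {
            "format": "pulseaf-bilstm-v1",
            "config": asdict(self.cfg),
            "input_dim": self.input_dim,
            "trained": self.trained,
            "history": self.history,
        }
        np.savez(
            path,
            _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            norm_mean=self.norm_mean,
            norm_sd=self.norm_sd,
            **self.params,
        )

    @classmethod
    def load(cls, path: str) -> "BiLSTMClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            if meta.get("format") != "pulseaf-bilstm-v1":
                raise ValueError(f"{path}: not a pulseaf model checkpoint")
            model = cls(NetConfig(**meta["config"]), meta["input_dim"])
            for k in model.params:
                model.params[k] = data[k]
            model.norm_mean = data["norm_mean"]
            model.norm_sd = data["norm_sd"]
            model.trained = meta["trained"]
            model.history = meta["history"]
        return model


# ---------------------------------------------------------------------------
# module-level operations


def stack_features(features: list[FeatureMatrix]) -> np.ndarray:
    """(n_records, frames, bands + n_timedomain): the per-record time-domain
    vector is broadcast across frames and appended to each frame."""
    mats = []
    for fm in features:
        tf = np.tile(fm.time_features, (fm.n_frames, 1))
        mats.append(np.concatenate([fm.values, tf], axis=1))
    shapes = {m.shape for m in mats}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent feature shapes across records: {shapes}")
    return np.stack(mats)


def encode_labels(labels: list[str]) -> np.ndarray:
    try:
        return np.array([LABEL_ORDER.index(lab) for lab in labels], dtype=int)
    except ValueError as exc:
        raise ValueError(f"labels must be in {LABEL_ORDER}") from exc


def build_model(cfg: NetConfig, input_shape: tuple[int, int]) -> BiLSTMClassifier:
    """Untrained model for feature matrices of shape (frames, features).
    Same seed => identical initial weights."""
    if len(input_shape) != 2 or min(input_shape) < 1:
        raise ValueError(f"input_shape must be (frames, features), got {input_shape}")
    return BiLSTMClassifier(cfg, input_dim=int(input_shape[1]))


def lr_schedule(cfg: NetConfig, epoch: int) -> float:
    """lr at a 0-based epoch: initial_lr * lrdf ** floor(epoch / period)."""
    return cfg.initial_lr * cfg.lrdf ** (epoch // cfg.decay_period_epochs)


def train(
    model: BiLSTMClassifier,
    features: list[FeatureMatrix] | np.ndarray,
    labels: list[str] | np.ndarray,
    cfg: NetConfig | None = None,
) -> BiLSTMClassifier:
    """Train in place with Adam and the stepwise lr schedule; returns the model.

    Input standardization statistics are fitted on this training set.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or model.cfg
    X = features if isinstance(features, np.ndarray) else stack_features(features)
    y = labels if isinstance(labels, np.ndarray) else encode_labels(list(labels))
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError(
            "invalid training set: need at least 2 examples of each class, "
            f"got counts {dict(zip(classes.tolist(), counts.tolist()))}"
        )

    flat = X.reshape(-1, X.shape[-1])
    model.norm_mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    model.norm_sd = np.where(sd > 0, sd, 1.0)

    rng = np.random.default_rng(cfg.seed + 1)
    n = X.shape[0]
    for epoch in range(cfg.max_epochs):
        lr = lr_schedule(cfg, epoch)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            loss, grads = model.loss_and_grads(X[sel], y[sel])
            model._adam_step(grads, lr)
            epoch_losses.append(loss)
        probs = _predict_probs(model, X, cfg.batch_size)
        acc = float(np.mean(probs.argmax(axis=1) == y))
        model.history["loss"].append(float(np.mean(epoch_losses)))
        model.history["accuracy"].append(acc)
        model.history["lr"].append(lr)
    model.trained = True
    return model


def _predict_probs(model: BiLSTMClassifier, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = [model.forward(X[s : s + batch_size]) for s in range(0, X.shape[0], batch_size)]
    return np.concatenate(out)


def predict(
    model: BiLSTMClassifier, features: list[FeatureMatrix] | np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Predicted labels and class probabilities.  Exact probability ties
    resolve toward NSR (index 0)."""
    X = features if isinstance(features, np.ndarray) else stack_features(features)
    if X.shape[-1] != model.input_dim:
        raise ValueError(
            f"feature dimension {X.shape[-1]} does not match model input {model.input_dim}"
        )
    probs = _predict_probs(model, X)
    idx = probs.argmax(axis=1)  # first max -> NSR on ties
    return [LABEL_ORDER[k] for k in idx], probs


def suggest_lr(lrs: np.ndarray, losses: np.ndarray) -> float:
    """Suggested initial lr from a range-test curve: minimizer of the
    5-point moving average over the finite prefix; an (effectively)
    constant curve falls back to the smallest lr."""
    lrs = np.asarray(lrs, dtype=float)
    losses = np.asarray(losses, dtype=float)
    bad = ~np.isfinite(losses)
    if bad.any():
        cut = int(np.flatnonzero(bad)[0])
        lrs, losses = lrs[:cut], losses[:cut]
    if losses.size == 0:
        raise ValueError("no finite losses in the range test")
    kernel = np.ones(min(5, losses.size))
    smooth = np.convolve(losses, kernel, mode="same") / np.convolve(
        np.ones_like(losses), kernel, mode="same"
    )
    span = float(smooth.max() - smooth.min())
    if span <= 1e-12 * max(1.0, float(np.abs(smooth).max())):
        return float(lrs[0])
    return float(lrs[int(np.argmin(smooth))])


def lr_range_test(
    model: BiLSTMClassifier,
    features: list[FeatureMatrix] | np.ndarray,
    labels: list[str] | np.ndarray,
    lr_start: float = 1e-5,
    lr_end: float = 1.0,
    n_steps: int = 50,
    batch_size: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Geometric lr sweep on a fresh copy of the model, one Adam step per
    batch, loss retained per batch.  Returns (lr grid, loss curve,
    suggested lr); the model passed in is not modified."""
    if not lr_start < lr_end:
        raise ValueError("need lr_start < lr_end")
    if n_steps < 10:
        raise ValueError("n_steps must be >= 10")
    X = features if isinstance(features, np.ndarray) else stack_features(features)
    y = labels if isinstance(labels, np.ndarray) else encode_labels(list(labels))
    probe = model.clone()
    if not probe.trained:
        flat = X.reshape(-1, X.shape[-1])
        probe.norm_mean = flat.mean(axis=0)
        sd = flat.std(axis=0)
        probe.norm_sd = np.where(sd > 0, sd, 1.0)
    bs = batch_size or model.cfg.batch_size
    rng = np.random.default_rng(model.cfg.seed if seed is None else seed)
    lrs = np.geomspace(lr_start, lr_end, n_steps)
    losses = np.empty(n_steps)
    n = X.shape[0]
    for k, lr in enumerate(lrs):
        sel = rng.choice(n, size=min(bs, n), replace=False)
        loss, grads = probe.loss_and_grads(X[sel], y[sel])
        losses[k] = loss
        if not np.isfinite(loss):
            losses[k + 1 :] = np.nan
            break
        probe._adam_step(grads, lr)
    return lrs, losses, suggest_lr(lrs, losses)
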