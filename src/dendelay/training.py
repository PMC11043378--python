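"""Hardware-aware training: surrogate-gradient BPTT with RRAM noise injection.

Gradients are computed analytically (hand-derived backpropagation through
time) rather than through an autodiff framework:

* For networks read out through non-spiking leaky integrators with a
  max-over-time cross-entropy loss, the membrane is linear in the weights, so
  the gradient is exact (up to the max subgradient).
* For spiking outputs, the hard threshold is backpropagated through a
  surrogate derivative (boxcar or fast-sigmoid), with the membrane gradient
  blocked at reset — the standard BPTT treatment of LIF neurons.

Device variability is injected with the straight-through estimator (STE):
each batch, the forward and backward passes run on weights perturbed by the
RRAM noise model (Gaussian, sigma = 10% of the layer's maximum absolute
weight by default), but the resulting gradient updates the clean underlying
weights.  Training runs a noise-free pre-training phase first, then the
noise-injected phase; frozen delay banks are never updated.  The same
machinery supports retraining around faulty (stuck-at-zero) weight devices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .devices import RRAMNoiseModel, perturb_weights
from .network import DendriticLayer, LIFParams, _apply_delays_array
from .srnn import SRNNConfig, SRNNWeights

__all__ = [
    "SurrogateGrad",
    "TrainConfig",
    "TrainResult",
    "DelayNetClassifier",
    "DelayNetDetector",
    "SRNNClassifier",
    "multiclass_loss",
    "binary_spikecount_decision",
    "select_spike_threshold",
    "noisy_forward_ste",
    "train",
    "evaluate_under_noise",
    "retrain_with_faulty_devices",
    "balanced_accuracy",
]


# ---------------------------------------------------------------------------
# surrogate gradients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateGrad:
    """Pseudo-derivative of the spike nonlinearity at membrane value ``v``.

    ``boxcar``: derivative 1 inside ``|v - threshold| < 0.5 * width * threshold``,
    0 outside.  ``fast_sigmoid``: ``1 / (1 + steepness * |v - threshold|)**2``,
    nonzero everywhere (no dead zones, useful for sparse single-output nets).
    """

    kind: str = "boxcar"
    param: float = 1.0  # boxcar width (in thresholds) or fast-sigmoid steepness

    def __post_init__(self) -> None:
        if self.kind not in ("boxcar", "fast_sigmoid"):
            raise ValueError(f"unknown surrogate kind {self.kind!r}")
        if not self.param > 0:
            raise ValueError("surrogate parameter must be positive")

    def __call__(self, v: np.ndarray, threshold: float) -> np.ndarray:
        x = v - threshold
        if self.kind == "boxcar":
            return (np.abs(x) < 0.5 * self.param * threshold).astype(float)
        return 1.0 / (1.0 + self.param * np.abs(x)) ** 2


# ---------------------------------------------------------------------------
# losses and decisions
# ---------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def multiclass_loss(membrane: np.ndarray, labels: np.ndarray) -> float:
    """Cross-entropy with logits = per-class maximum membrane over time.

    ``membrane``: ``(outputs, bins)`` or ``(batch, outputs, bins)``.
    """
    traces = np.asarray(membrane, dtype=float)
    if traces.ndim == 2:
        traces = traces[None]
        labels = np.asarray([labels])
    logits = traces.max(axis=-1)
    p = _softmax(logits)
    return float(-np.mean(np.log(p[np.arange(len(labels)), labels] + 1e-12)))


def binary_spikecount_decision(spike_counts: np.ndarray, threshold: float) -> np.ndarray:
    """Anomaly (1) iff the output spike count exceeds ``threshold``, else normal (0)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (np.asarray(spike_counts) > threshold).astype(np.int64)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class recalls (robust to class imbalance)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    recalls = [
        (y_pred[y_true == cls] == cls).mean()
        for cls in np.unique(y_true)
    ]
    return float(np.mean(recalls))


def select_spike_threshold(spike_counts: np.ndarray, labels: np.ndarray) -> int:
    """Sweep integer count thresholds, return the balanced-accuracy argmax."""
    counts = np.asarray(spike_counts)
    best_thr, best_score = 0, -1.0
    for thr in range(int(counts.max()) + 1):
        score = balanced_accuracy(labels, binary_spikecount_decision(counts, thr))
        if score > best_score:
            best_thr, best_score = thr, score
    return best_thr


# ---------------------------------------------------------------------------
# trainable models (shared interface: prepare / loss_and_grad / predict / score)
# ---------------------------------------------------------------------------

def _leaky_filter(x: np.ndarray, alpha: float) -> np.ndarray:
    """Causal first-order low-pass along the last axis: y[t] = alpha*y[t-1] + x[t]."""
    y = np.empty_like(x, dtype=float)
    acc = np.zeros(x.shape[:-1])
    for t in range(x.shape[-1]):
        acc = alpha * acc + x[..., t]
        y[..., t] = acc
    return y


class DelayNetClassifier:
    """Delay network with leaky-integrator outputs, max-membrane cross-entropy.

    The membrane is linear in the weights, so gradients are exact:
    ``u[b,o,t] = sum_{c,i} w[c,i,o] * K[b,c,i,t]`` with ``K`` the
    leaky-filtered, delay-expanded input.
    """

    def __init__(self, layer: DendriticLayer, neuron: LIFParams):
        self.layer = layer
        self.neuron = neuron
        self.fault_masks: list[np.ndarray] | None = None

    # -- weight plumbing ----------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [self.layer.weights.copy()]

    def set_weights(self, ws: Sequence[np.ndarray]) -> None:
        self.layer.weights = self._clamp(list(ws))[0]

    def _clamp(self, ws: list[np.ndarray]) -> list[np.ndarray]:
        if self.fault_masks is None:
            return ws
        return [np.where(m, 0.0, w) for w, m in zip(ws, self.fault_masks)]

    # -- features -----------------------------------------------------------
    def prepare(self, counts: np.ndarray) -> np.ndarray:
        """Delay-expand and leaky-filter a batch ``(B, C, T)`` of count arrays."""
        expanded = _apply_delays_array(np.asarray(counts, float), self.layer.bank.bin_offsets)
        return _leaky_filter(expanded, self.neuron.alpha)

    # -- training -----------------------------------------------------------
    def loss_and_grad(
        self, ws: Sequence[np.ndarray], features: np.ndarray, labels: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        (w,) = self._clamp(list(ws))
        membrane = np.einsum("bcit,cio->bot", features, w)
        logits = membrane.max(axis=-1)
        t_star = membrane.argmax(axis=-1)  # (B, O)
        p = _softmax(logits)
        batch = len(labels)
        loss = float(-np.mean(np.log(p[np.arange(batch), labels] + 1e-12)))
        g_logits = p.copy()
        g_logits[np.arange(batch), labels] -= 1.0
        g_logits /= batch
        # gather K at the per-(sample, output) argmax bin
        k_star = np.take_along_axis(
            features[:, :, :, None, :],
            t_star[:, None, None, :, None],
            axis=-1,
        )[..., 0]  # (B, C, I, O)
        grad = np.einsum("bo,bcio->cio", g_logits, k_star)
        return loss, self._clamp([grad])

    # -- inference ----------------------------------------------------------
    def predict_with(self, ws: Sequence[np.ndarray], features: np.ndarray) -> np.ndarray:
        (w,) = self._clamp(list(ws))
        membrane = np.einsum("bcit,cio->bot", features, w)
        return membrane.max(axis=-1).argmax(axis=-1)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.predict_with(self.get_weights(), features)

    def score(self, ws: Sequence[np.ndarray], features: np.ndarray, labels: np.ndarray) -> float:
        return float((self.predict_with(ws, features) == labels).mean())


class DelayNetDetector:
    """Single spiking LIF output trained on spike-count targets (binary task).

    The loss is a squared error between the output spike count and a target
    count (0 for normal, ``target_count`` for anomaly); the threshold
    nonlinearity is backpropagated through a surrogate derivative.  At
    inference, an integer count threshold chosen on the validation split
    turns counts into normal/anomaly decisions.
    """

    def __init__(
        self,
        layer: DendriticLayer,
        neuron: LIFParams,
        surrogate: SurrogateGrad = SurrogateGrad("fast_sigmoid", 5.0),
        target_count: float = 4.0,
    ):
        if layer.n_outputs != 1:
            raise ValueError("the spike-count detector has a single output neuron")
        self.layer = layer
        self.neuron = neuron
        self.surrogate = surrogate
        self.target_count = target_count
        self.decision_threshold: int = 0
        self.fault_masks: list[np.ndarray] | None = None

    get_weights = DelayNetClassifier.get_weights
    set_weights = DelayNetClassifier.set_weights
    _clamp = DelayNetClassifier._clamp

    def prepare(self, counts: np.ndarray) -> np.ndarray:
        """Delay-expand a batch ``(B, C, T)``; LIF dynamics run per forward pass."""
        return _apply_delays_array(np.asarray(counts, float), self.layer.bank.bin_offsets)

    def _lif_forward(self, w: np.ndarray, expanded: np.ndarray):
        currents = np.einsum("bcit,cio->bot", expanded, w)
        alpha = self.neuron.alpha
        n_bins = currents.shape[-1]
        v = np.full(currents.shape[:-1], self.neuron.v_reset)
        v_pre = np.zeros_like(currents)
        spikes = np.zeros_like(currents)
        for t in range(n_bins):
            v = alpha * v + currents[..., t]
            v_pre[..., t] = v
            fired = v >= self.neuron.v_threshold
            spikes[..., t] = fired
            v = np.where(fired, self.neuron.v_reset, v)
        return v_pre, spikes

    def loss_and_grad(
        self, ws: Sequence[np.ndarray], features: np.ndarray, labels: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        (w,) = self._clamp(list(ws))
        v_pre, spikes = self._lif_forward(w, features)
        counts = spikes.sum(axis=-1)  # (B, 1)
        target = np.where(np.asarray(labels)[:, None] > 0, self.target_count, 0.0)
        batch = len(labels)
        loss = float(0.5 * np.mean((counts - target) ** 2))
        if not math.isfinite(loss):
            raise FloatingPointError("non-finite loss; diverged forward pass")
        g_count = (counts - target) / batch  # dL/ds[t] for every t
        alpha = self.neuron.alpha
        sd = self.surrogate(v_pre, self.neuron.v_threshold)
        lam = np.zeros_like(v_pre)
        carry = np.zeros_like(g_count)
        for t in range(v_pre.shape[-1] - 1, -1, -1):
            lam_t = g_count * sd[..., t] + carry
            lam[..., t] = lam_t
            # membrane gradient blocked at reset; alpha leak otherwise
            carry = alpha * lam_t * (1.0 - spikes[..., t])
        grad = np.einsum("bot,bcit->cio", lam, features)
        return loss, self._clamp([grad])

    def spike_counts(self, ws: Sequence[np.ndarray], features: np.ndarray) -> np.ndarray:
        (w,) = self._clamp(list(ws))
        _, spikes = self._lif_forward(w, features)
        return spikes.sum(axis=-1)[:, 0]

    def predict_with(self, ws: Sequence[np.ndarray], features: np.ndarray) -> np.ndarray:
        return binary_spikecount_decision(
            self.spike_counts(ws, features), self.decision_threshold
        )

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.predict_with(self.get_weights(), features)

    def calibrate_threshold(self, features: np.ndarray, labels: np.ndarray) -> int:
        """Pick the validation-optimal count threshold (balanced accuracy)."""
        counts = self.spike_counts(self.get_weights(), features)
        self.decision_threshold = select_spike_threshold(counts, labels)
        return self.decision_threshold

    def score(self, ws: Sequence[np.ndarray], features: np.ndarray, labels: np.ndarray) -> float:
        counts = self.spike_counts(ws, features)
        thr = select_spike_threshold(counts, labels)
        return balanced_accuracy(labels, binary_spikecount_decision(counts, thr))

    def score_fixed(self, ws, features, labels) -> float:
        """Balanced accuracy at the already-calibrated decision threshold."""
        return balanced_accuracy(labels, self.predict_with(ws, features))


class SRNNClassifier:
    """Recurrent spiking baseline with max-membrane cross-entropy readout.

    BPTT through the hidden LIF layer uses the surrogate derivative at each
    spike and blocks the membrane gradient at reset; the one-step-delayed
    recurrence contributes ``W_rec``-projected gradients from the next bin.
    """

    def __init__(
        self,
        config: SRNNConfig,
        weights: SRNNWeights | None = None,
        surrogate: SurrogateGrad = SurrogateGrad("boxcar", 1.0),
        seed: int = 0,
    ):
        self.config = config
        self.weights = weights or SRNNWeights.initialize(config, seed=seed)
        self.weights.validate(config)
        self.surrogate = surrogate
        self.fault_masks: list[np.ndarray] | None = None

    def get_weights(self) -> list[np.ndarray]:
        return [self.weights.w_in.copy(), self.weights.w_rec.copy(), self.weights.w_out.copy()]

    def set_weights(self, ws: Sequence[np.ndarray]) -> None:
        w_in, w_rec, w_out = self._clamp(list(ws))
        self.weights = SRNNWeights(w_in, w_rec, w_out)

    _clamp = DelayNetClassifier._clamp

    def prepare(self, counts: np.ndarray) -> np.ndarray:
        return np.asarray(counts, dtype=float)

    def _forward(self, ws: list[np.ndarray], x: np.ndarray):
        w_in, w_rec, w_out = ws
        cfg = self.config
        batch, _, n_bins = x.shape
        alpha_h, alpha_o = cfg.hidden.alpha, cfg.output.alpha
        v = np.full((batch, cfg.n_hidden), cfg.hidden.v_reset)
        s_prev = np.zeros((batch, cfg.n_hidden))
        u = np.full((batch, cfg.n_out), cfg.output.v_reset)
        v_pre = np.zeros((batch, cfg.n_hidden, n_bins))
        spikes = np.zeros((batch, cfg.n_hidden, n_bins))
        out_membrane = np.zeros((batch, cfg.n_out, n_bins))
        for t in range(n_bins):
            v = alpha_h * v + x[:, :, t] @ w_in + s_prev @ w_rec
            v_pre[:, :, t] = v
            fired = (v >= cfg.hidden.v_threshold).astype(float)
            spikes[:, :, t] = fired
            v = np.where(fired > 0, cfg.hidden.v_reset, v)
            u = alpha_o * u + fired @ w_out
            out_membrane[:, :, t] = u
            s_prev = fired
        return v_pre, spikes, out_membrane

    def loss_and_grad(
        self, ws: Sequence[np.ndarray], features: np.ndarray, labels: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        w_in, w_rec, w_out = self._clamp(list(ws))
        x = features
        cfg = self.config
        batch, _, n_bins = x.shape
        v_pre, spikes, out_membrane = self._forward([w_in, w_rec, w_out], x)
        logits = out_membrane.max(axis=-1)
        t_star = out_membrane.argmax(axis=-1)
        p = _softmax(logits)
        loss = float(-np.mean(np.log(p[np.arange(batch), labels] + 1e-12)))
        g_logits = p.copy()
        g_logits[np.arange(batch), labels] -= 1.0
        g_logits /= batch

        alpha_h, alpha_o = cfg.hidden.alpha, cfg.output.alpha
        sd = self.surrogate(v_pre, cfg.hidden.v_threshold)
        g_in = np.zeros_like(w_in)
        g_rec = np.zeros_like(w_rec)
        g_out = np.zeros_like(w_out)
        mu = np.zeros((batch, cfg.n_out))      # dL/du[t] accumulated backward
        lam_next = np.zeros((batch, cfg.n_hidden))  # dL/dv_pre[t+1]
        for t in range(n_bins - 1, -1, -1):
            mu = alpha_o * mu
            hit = t_star == t  # (B, O): bins where the max was attained
            mu = mu + np.where(hit, g_logits, 0.0)
            # dL/ds_h[t]: through W_out now, and through W_rec into bin t+1
            g_s = mu @ w_out.T + lam_next @ w_rec.T
            lam = g_s * sd[:, :, t] + alpha_h * lam_next * (1.0 - spikes[:, :, t])
            g_out += spikes[:, :, t].T @ mu
            g_in += x[:, :, t].T @ lam
            if t > 0:
                g_rec += spikes[:, :, t - 1].T @ lam
            lam_next = lam
        return loss, self._clamp([g_in, g_rec, g_out])

    def predict_with(self, ws: Sequence[np.ndarray], features: np.ndarray) -> np.ndarray:
        _, _, out_membrane = self._forward(self._clamp(list(ws)), features)
        return out_membrane.max(axis=-1).argmax(axis=-1)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.predict_with(self.get_weights(), features)

    def score(self, ws: Sequence[np.ndarray], features: np.ndarray, labels: np.ndarray) -> float:
        return float((self.predict_with(ws, features) == labels).mean())


# ---------------------------------------------------------------------------
# STE forward/backward, optimizer, training loop
# ---------------------------------------------------------------------------

def noisy_forward_ste(
    model,
    features: np.ndarray,
    labels: np.ndarray,
    noise: RRAMNoiseModel,
    rng: int | np.random.Generator,
) -> tuple[float, list[np.ndarray]]:
    """Forward/backward at noise-perturbed weights; gradients for clean weights.

    With ``relative_sigma == 0`` this is bit-identical to a plain forward
    pass.  Noise is freshly sampled per call (i.e. per batch).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ws = model.get_weights()
    if noise.relative_sigma > 0:
        ws = [perturb_weights(w, noise, rng) for w in ws]
    return model.loss_and_grad(ws, features, labels)


class Adam:
    """Adaptive-moment gradient descent over a list of weight arrays."""

    def __init__(self, shapes, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, ws: list[np.ndarray], grads: list[np.ndarray]) -> list[np.ndarray]:
        self.t += 1
        out = []
        for k, (w, g) in enumerate(zip(ws, grads)):
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            out.append(w - self.lr * m_hat / (np.sqrt(v_hat) + self.eps))
        return out


@dataclass
class TrainConfig:
    """Optimization settings for the hardware-aware training loop."""

    epochs: int = 50
    pretrain_epochs: int | None = None  # default: 20% of epochs
    batch_size: int = 64
    learning_rate: float = 1e-2
    weight_decay: float = 0.0  # decoupled L2 shrinkage per step
    noise: RRAMNoiseModel = field(default_factory=lambda: RRAMNoiseModel(0.10))
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.pretrain_epochs is None:
            self.pretrain_epochs = max(1, int(round(0.2 * self.epochs))) if self.epochs else 0
        if self.pretrain_epochs > self.epochs:
            raise ValueError("pretrain_epochs cannot exceed epochs")


@dataclass
class TrainResult:
    model: object
    metrics: list[dict]
    best_val_score: float
    best_weights: list[np.ndarray]

    def metrics_frame(self):
        import pandas as pd

        return pd.DataFrame(self.metrics)


def _split(n: int, val_fraction: float, rng: np.random.Generator):
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    return order[n_val:], order[:n_val]


def train(model, dataset, config: TrainConfig) -> TrainResult:
    """Two-phase hardware-aware training with validation-based model selection.

    ``dataset`` is ``(X, y)`` with ``X`` of shape ``(N, channels, bins)``.
    Phase 1 runs ``pretrain_epochs`` without noise to initialize the
    hardware-aware phase; phase 2 injects fresh weight noise every batch via
    the straight-through estimator.  The weights with the best validation
    score are restored at the end.  Delay banks are frozen by construction
    and never touched.
    """
    X, y = (dataset.counts, dataset.labels) if hasattr(dataset, "counts") else dataset
    X = np.asarray(X)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("dataset is empty")
    if np.unique(y).size < 2:
        raise ValueError("dataset must contain at least two classes")
    rng = np.random.default_rng(config.seed)
    noise_rng = np.random.default_rng(config.seed + 1)
    train_idx, val_idx = _split(len(X), config.val_fraction, rng)
    feats = model.prepare(X)
    f_train, y_train = feats[train_idx], y[train_idx]
    f_val, y_val = feats[val_idx], y[val_idx]

    ws = model.get_weights()
    opt = Adam([w.shape for w in ws], lr=config.learning_rate)
    zero_noise = RRAMNoiseModel(0.0)
    metrics: list[dict] = []
    best_score, best_ws = -np.inf, [w.copy() for w in ws]
    n_train = len(f_train)
    for epoch in range(config.epochs):
        phase = "pretrain" if epoch < config.pretrain_epochs else "noisy"
        noise = zero_noise if phase == "pretrain" else config.noise
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            model.set_weights(ws)
            loss, grads = noisy_forward_ste(
                model, f_train[idx], y_train[idx], noise, noise_rng
            )
            ws = opt.step(ws, grads)
            if config.weight_decay:
                decay = 1.0 - config.learning_rate * config.weight_decay
                ws = [w * decay for w in ws]
            epoch_loss += loss * len(idx)
        model.set_weights(ws)
        ws = model.get_weights()  # pick up fault clamping
        train_score = model.score(ws, f_train, y_train)
        val_score = model.score(ws, f_val, y_val)
        metrics.append(
            {
                "epoch": epoch,
                "phase": phase,
                "loss": epoch_loss / n_train,
                "train_score": train_score,
                "val_score": val_score,
                "sigma": noise.relative_sigma,
            }
        )
        if val_score > best_score:
            best_score = val_score
            best_ws = [w.copy() for w in ws]
    model.set_weights(best_ws)
    if hasattr(model, "calibrate_threshold"):
        model.calibrate_threshold(f_val, y_val)
    return TrainResult(model=model, metrics=metrics, best_val_score=best_score, best_weights=best_ws)


def evaluate_under_noise(
    model,
    features: np.ndarray,
    labels: np.ndarray,
    relative_sigma: float,
    n_trials: int = 3,
    seed: int = 0,
) -> dict:
    """Accuracy under per-trial weight perturbations: mean, std, per-trial values."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    noise = RRAMNoiseModel(relative_sigma)
    clean = model.get_weights()
    scores = []
    score_fn = getattr(model, "score_fixed", model.score)
    for _ in range(n_trials):
        ws = clean if relative_sigma == 0 else [perturb_weights(w, noise, rng) for w in clean]
        scores.append(score_fn(ws, features, labels))
    scores = np.asarray(scores)
    return {
        "relative_sigma": relative_sigma,
        "mean": float(scores.mean()),
        "std": float(scores.std()),
        "scores": scores,
    }


def retrain_with_faulty_devices(model, fault_masks, dataset, config: TrainConfig) -> TrainResult:
    """Clamp masked weights to zero (stuck devices) and retrain the rest.

    Masked entries stay exactly zero through every forward pass and receive
    zero gradient.  A mask covering an entire weight array is rejected.
    """
    ws = model.get_weights()
    masks = [np.asarray(m, dtype=bool) for m in fault_masks]
    if len(masks) != len(ws):
        raise ValueError("one fault mask per weight array is required")
    for m, w in zip(masks, ws):
        if m.shape != w.shape:
            raise ValueError(f"mask shape {m.shape} does not match weights {w.shape}")
        if m.all():
            raise ValueError("an entirely faulty weight array cannot be retrained")
    model.fault_masks = masks
    model.set_weights(ws)  # apply the clamp immediately
    return train(model, dataset, config)
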