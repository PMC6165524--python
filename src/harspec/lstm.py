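"""Stacked LSTM classifier over spectral feature vectors.

The recurrent cell follows the peephole-style gate equations

    i_t = σ(W_xi x_t + W_hi c_{t−1} + b_i)
    f_t = σ(W_xf x_t + W_hf h_{t−1} + W_cf c_{t−1} + b_f)
    c_t = f_t ⊗ c_{t−1} + i_t ⊗ tanh(W_xc x_t + W_hc h_{t−1} + b_c)
    o_t = σ(W_xo x_t + W_ho h_{t−1} + W_co c_t + b_o)
    h_t = o_t ⊗ tanh(c_t)

where the input gate is driven by the previous cell state (through W_hi)
and the forget/output gates carry full-matrix peephole terms W_cf, W_co.
A ``peephole=False`` switch falls back to the standard cell (input gate on
h_{t−1}, no W_cf/W_co terms).  Five such layers of 15 units are stacked;
the last layer's final hidden state passes through a ReLU dense stage and
a softmax head.

Feature vectors are static, so each row is reshaped into a short sequence
before entering the recurrence — by default 4 time steps, one per feature
block (SA, LeA, SG, LG), with (S+L)/2 features per step.

Training minimises softmax cross-entropy with an L2 penalty using the
Adam optimiser and hand-derived backpropagation through time (verified
against finite differences in the test suite).  Everything runs in
float64 NumPy, so runs are deterministic given the seed on a fixed
platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np

from .features import FeatureSet

__all__ = [
    "LstmConfig",
    "LstmCellWeights",
    "StackedLstmClassifier",
    "lstm_cell_step",
    "init_cell_weights",
    "train",
    "predict",
]

GATE_WEIGHT_NAMES = ("W_xi", "W_hi", "W_xf", "W_hf", "W_cf",
                     "W_xc", "W_hc", "W_xo", "W_ho", "W_co")
GATE_BIAS_NAMES = ("b_i", "b_f", "b_c", "b_o")


@dataclass
class LstmConfig:
    """Training configuration (defaults follow the reference experiment).

    ``sequence_reshape`` is ``(steps, features_per_step)``; ``None`` means
    4 steps — one per feature block — with equal split of the vector.
    ``mini_batch_size`` is capped at the dataset size at fit time.
    """

    hidden_units: int = 15
    stacked_layers: int = 5
    learning_rate: float = 0.003
    mini_batch_size: int = 8000
    l2_lambda: float = 1e-4
    loss_target: float = 0.001
    max_epochs: int = 300
    seed: int = 0
    sequence_reshape: tuple[int, int] | None = None
    peephole: bool = True
    dense_units: int = 15
    log_transform: bool = True
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if not (0 < self.learning_rate < 1):
            raise ValueError("learning_rate must lie in (0, 1)")
        if self.hidden_units < 1 or self.stacked_layers < 1:
            raise ValueError("hidden_units and stacked_layers must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class LstmCellWeights:
    """One layer's gate matrices, biases and (externally held) state.

    ``W_hi`` multiplies c_{t−1} in peephole mode and h_{t−1} otherwise;
    both are (H, H) so the switch changes no shapes.
    """

    W_xi: np.ndarray
    W_hi: np.ndarray
    W_xf: np.ndarray
    W_hf: np.ndarray
    W_cf: np.ndarray
    W_xc: np.ndarray
    W_hc: np.ndarray
    W_xo: np.ndarray
    W_ho: np.ndarray
    W_co: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @property
    def hidden_units(self) -> int:
        return self.W_xi.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_xi.shape[1]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def init_cell_weights(input_dim: int, hidden_units: int,
                      rng: np.random.Generator) -> LstmCellWeights:
    """Uniform init scaled by fan-in: U(−1/√fan_in, 1/√fan_in)."""
    def mat(out_dim: int, in_dim: int) -> np.ndarray:
        bound = 1.0 / np.sqrt(in_dim)
        return rng.uniform(-bound, bound, size=(out_dim, in_dim))

    H, D = hidden_units, input_dim
    return LstmCellWeights(
        W_xi=mat(H, D), W_hi=mat(H, H),
        W_xf=mat(H, D), W_hf=mat(H, H), W_cf=mat(H, H),
        W_xc=mat(H, D), W_hc=mat(H, H),
        W_xo=mat(H, D), W_ho=mat(H, H), W_co=mat(H, H),
        b_i=np.zeros(H), b_f=np.ones(H), b_c=np.zeros(H), b_o=np.zeros(H),
    )


def lstm_cell_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
                   w: LstmCellWeights, peephole: bool = True,
                   return_cache: bool = False):
    """One step of the gate equations; accepts (D,) vectors or (B, D) batches.

    Returns ``(h_t, c_t)`` — or ``(h_t, c_t, cache)`` with the
    intermediates needed for backpropagation when ``return_cache``.
    """
    x = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=float))
    squeeze = np.asarray(x_t).ndim == 1
    if x.shape[1] != w.input_dim or h_prev.shape[1] != w.hidden_units \
            or c_prev.shape[1] != w.hidden_units:
        raise ValueError("shape mismatch between inputs/state and cell weights")

    rec_i = c_prev if peephole else h_prev
    i = _sigmoid(x @ w.W_xi.T + rec_i @ w.W_hi.T + w.b_i)
    a_f = x @ w.W_xf.T + h_prev @ w.W_hf.T + w.b_f
    if peephole:
        a_f = a_f + c_prev @ w.W_cf.T
    f = _sigmoid(a_f)
    g = np.tanh(x @ w.W_xc.T + h_prev @ w.W_hc.T + w.b_c)
    c = f * c_prev + i * g
    a_o = x @ w.W_xo.T + h_prev @ w.W_ho.T + w.b_o
    if peephole:
        a_o = a_o + c @ w.W_co.T
    o = _sigmoid(a_o)
    tanh_c = np.tanh(c)
    h = o * tanh_c

    if squeeze:
        h_out, c_out = h[0], c[0]
    else:
        h_out, c_out = h, c
    if not return_cache:
        return h_out, c_out
    cache = {"x": x, "h_prev": h_prev, "c_prev": c_prev,
             "i": i, "f": f, "g": g, "o": o, "c": c, "tanh_c": tanh_c}
    return h_out, c_out, cache


def _cell_backward(dh: np.ndarray, dc_carry: np.ndarray, cache: dict,
                   w: LstmCellWeights, grads: dict[str, np.ndarray],
                   peephole: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backprop one cell step; accumulates weight grads, returns
    (dx, dh_prev, dc_prev)."""
    x, h_prev, c_prev = cache["x"], cache["h_prev"], cache["c_prev"]
    i, f, g, o, c, tanh_c = (cache["i"], cache["f"], cache["g"],
                             cache["o"], cache["c"], cache["tanh_c"])

    do = dh * tanh_c
    da_o = do * o * (1 - o)
    dc = dc_carry + dh * o * (1 - tanh_c ** 2)
    if peephole:
        dc = dc + da_o @ w.W_co
        grads["W_co"] += da_o.T @ c
    df = dc * c_prev
    da_f = df * f * (1 - f)
    di = dc * g
    da_i = di * i * (1 - i)
    dg = dc * i
    da_c = dg * (1 - g ** 2)

    dc_prev = dc * f
    if peephole:
        dc_prev = dc_prev + da_i @ w.W_hi + da_f @ w.W_cf
        dh_prev = da_f @ w.W_hf + da_c @ w.W_hc + da_o @ w.W_ho
        grads["W_hi"] += da_i.T @ c_prev
        grads["W_cf"] += da_f.T @ c_prev
    else:
        dh_prev = da_i @ w.W_hi + da_f @ w.W_hf + da_c @ w.W_hc + da_o @ w.W_ho
        grads["W_hi"] += da_i.T @ h_prev
    dx = da_i @ w.W_xi + da_f @ w.W_xf + da_c @ w.W_xc + da_o @ w.W_xo

    grads["W_xi"] += da_i.T @ x
    grads["W_xf"] += da_f.T @ x
    grads["W_hf"] += da_f.T @ h_prev
    grads["W_xc"] += da_c.T @ x
    grads["W_hc"] += da_c.T @ h_prev
    grads["W_xo"] += da_o.T @ x
    grads["W_ho"] += da_o.T @ h_prev
    grads["b_i"] += da_i.sum(axis=0)
    grads["b_f"] += da_f.sum(axis=0)
    grads["b_c"] += da_c.sum(axis=0)
    grads["b_o"] += da_o.sum(axis=0)
    return dx, dh_prev, dc_prev


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class StackedLstmClassifier:
    """Multi-layer LSTM with a ReLU dense stage and softmax output.

    Parameters are created lazily at :meth:`fit` time once the input
    width and class list are known.  Use the module-level :func:`train`
    and :func:`predict` helpers to work directly with ``FeatureSet``s.
    """

    def __init__(self, cfg: LstmConfig | None = None) -> None:
        self.cfg = cfg or LstmConfig()
        self.layers: list[LstmCellWeights] = []
        self.W_d1 = self.b_d1 = self.W_d2 = self.b_d2 = None
        self.classes_: list[str] | None = None
        self.feature_mean_ = None
        self.feature_std_ = None
        self.n_features_: int | None = None
        self.history_: list[dict] = []

    # -- parameter bookkeeping -------------------------------------------

    def _init_params(self, n_features: int, n_classes: int) -> None:
        cfg = self.cfg
        steps, width = self._reshape_dims(n_features)
        rng = np.random.default_rng(cfg.seed)
        self.layers = []
        in_dim = width
        for _ in range(cfg.stacked_layers):
            self.layers.append(init_cell_weights(in_dim, cfg.hidden_units, rng))
            in_dim = cfg.hidden_units
        bound1 = 1.0 / np.sqrt(cfg.hidden_units)
        self.W_d1 = rng.uniform(-bound1, bound1, size=(cfg.dense_units, cfg.hidden_units))
        self.b_d1 = np.zeros(cfg.dense_units)
        bound2 = 1.0 / np.sqrt(cfg.dense_units)
        self.W_d2 = rng.uniform(-bound2, bound2, size=(n_classes, cfg.dense_units))
        self.b_d2 = np.zeros(n_classes)
        self.n_features_ = n_features

    def _reshape_dims(self, n_features: int) -> tuple[int, int]:
        if self.cfg.sequence_reshape is not None:
            steps, width = self.cfg.sequence_reshape
        else:
            steps = 4 if n_features % 4 == 0 else 1
            width = n_features // steps
        if steps * width != n_features:
            raise ValueError(
                f"sequence_reshape {steps}x{width} does not tile {n_features} features")
        return steps, width

    def _params(self) -> list[tuple[object, str]]:
        out: list[tuple[object, str]] = []
        for layer in self.layers:
            for name in GATE_WEIGHT_NAMES + GATE_BIAS_NAMES:
                out.append((layer, name))
        out += [(self, "W_d1"), (self, "b_d1"), (self, "W_d2"), (self, "b_d2")]
        return out

    # -- preprocessing ----------------------------------------------------

    def _fit_scaler(self, X: np.ndarray) -> None:
        Z = np.log1p(X) if self.cfg.log_transform else X
        self.feature_mean_ = Z.mean(axis=0)
        std = Z.std(axis=0)
        std[std == 0] = 1.0
        self.feature_std_ = std

    def _transform(self, X: np.ndarray) -> np.ndarray:
        Z = np.log1p(X) if self.cfg.log_transform else np.asarray(X, dtype=float)
        return (Z - self.feature_mean_) / self.feature_std_

    def _to_sequences(self, X: np.ndarray) -> np.ndarray:
        steps, width = self._reshape_dims(X.shape[1])
        return X.reshape(X.shape[0], steps, width)

    # -- forward / backward ----------------------------------------------

    def _forward(self, seq: np.ndarray, with_cache: bool = False):
        B, T, _ = seq.shape
        H = self.cfg.hidden_units
        caches: list[list[dict]] = []
        current = seq
        for layer in self.layers:
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = []
            layer_caches = []
            for t in range(T):
                if with_cache:
                    h, c, cache = lstm_cell_step(current[:, t], h, c, layer,
                                                 self.cfg.peephole, return_cache=True)
                    layer_caches.append(cache)
                else:
                    h, c = lstm_cell_step(current[:, t], h, c, layer, self.cfg.peephole)
                hs.append(h)
            current = np.stack(hs, axis=1)
            caches.append(layer_caches)
        h_last = current[:, -1]
        z1 = h_last @ self.W_d1.T + self.b_d1
        a1 = np.maximum(z1, 0.0)
        logits = a1 @ self.W_d2.T + self.b_d2
        probs = _softmax(logits)
        if with_cache:
            return probs, {"caches": caches, "h_last": h_last, "z1": z1, "a1": a1,
                           "T": T, "B": B}
        return probs

    def _loss(self, probs: np.ndarray, Y: np.ndarray) -> float:
        ce = -np.mean(np.log(np.clip(probs[np.arange(len(Y)), Y], 1e-12, None)))
        l2 = 0.0
        for holder, name in self._params():
            if name.startswith("W"):
                l2 += float(np.sum(getattr(holder, name) ** 2))
        return ce + 0.5 * self.cfg.l2_lambda * l2

    def _gradients(self, seq: np.ndarray, Y: np.ndarray) -> tuple[float, list[np.ndarray]]:
        """Loss and gradient list aligned with :meth:`_params`."""
        cfg = self.cfg
        probs, fw = self._forward(seq, with_cache=True)
        B, T = fw["B"], fw["T"]
        loss = self._loss(probs, Y)

        dlogits = probs.copy()
        dlogits[np.arange(B), Y] -= 1.0
        dlogits /= B
        dW_d2 = dlogits.T @ fw["a1"]
        db_d2 = dlogits.sum(axis=0)
        da1 = dlogits @ self.W_d2
        dz1 = da1 * (fw["z1"] > 0)
        dW_d1 = dz1.T @ fw["h_last"]
        db_d1 = dz1.sum(axis=0)
        dh_top_last = dz1 @ self.W_d1

        layer_grads: list[dict[str, np.ndarray]] = []
        # dh_seq: gradient flowing into each layer's h outputs at every step.
        dh_seq = np.zeros((B, T, cfg.hidden_units))
        dh_seq[:, -1] = dh_top_last
        for li in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[li]
            grads = {name: np.zeros_like(getattr(layer, name))
                     for name in GATE_WEIGHT_NAMES + GATE_BIAS_NAMES}
            dh_next = np.zeros((B, cfg.hidden_units))
            dc_next = np.zeros((B, cfg.hidden_units))
            dx_seq = np.zeros((B, T, layer.input_dim))
            for t in range(T - 1, -1, -1):
                dh = dh_seq[:, t] + dh_next
                dx, dh_next, dc_next = _cell_backward(
                    dh, dc_next, fw["caches"][li][t], layer, grads, cfg.peephole)
                dx_seq[:, t] = dx
            layer_grads.append(grads)
            dh_seq = dx_seq  # feeds the layer below
        layer_grads.reverse()

        flat: list[np.ndarray] = []
        for li, layer in enumerate(self.layers):
            for name in GATE_WEIGHT_NAMES + GATE_BIAS_NAMES:
                g = layer_grads[li][name]
                if name.startswith("W"):
                    g = g + cfg.l2_lambda * getattr(layer, name)
                flat.append(g)
        for g, holder, name in ((dW_d1, self, "W_d1"), (db_d1, self, "b_d1"),
                                (dW_d2, self, "W_d2"), (db_d2, self, "b_d2")):
            if name.startswith("W"):
                g = g + cfg.l2_lambda * getattr(holder, name)
            flat.append(g)
        return loss, flat

    # -- training ---------------------------------------------------------

    def fit(self, X: np.ndarray, labels: np.ndarray) -> list[dict]:
        """Train with Adam; returns the per-epoch history.

        History rows are ``{"epoch", "loss", "accuracy"}`` with the loss
        (cross-entropy + L2 penalty) and training accuracy evaluated on
        the full set after each epoch.  Training stops at
        ``loss <= loss_target`` or after ``max_epochs``.
        """
        cfg = self.cfg
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        if X.shape[0] == 0:
            raise ValueError("features must be non-empty")
        self.classes_ = sorted(set(str(l) for l in labels))
        if len(self.classes_) < 2:
            raise ValueError("training requires at least 2 classes")
        class_index = {c: k for k, c in enumerate(self.classes_)}
        Y = np.array([class_index[str(l)] for l in labels])

        self._fit_scaler(X)
        seq_all = self._to_sequences(self._transform(X))
        self._init_params(X.shape[1], len(self.classes_))
        self.history_ = []
        if cfg.max_epochs == 0:
            return self.history_

        params = self._params()
        m = [np.zeros_like(getattr(h, n)) for h, n in params]
        v = [np.zeros_like(getattr(h, n)) for h, n in params]
        t_step = 0
        batch = min(cfg.mini_batch_size, X.shape[0])
        rng = np.random.default_rng(cfg.seed + 1)

        for epoch in range(1, cfg.max_epochs + 1):
            if batch >= X.shape[0]:
                batches = [np.arange(X.shape[0])]
            else:
                perm = rng.permutation(X.shape[0])
                batches = [perm[i:i + batch] for i in range(0, len(perm), batch)]
            for idx in batches:
                _, grads = self._gradients(seq_all[idx], Y[idx])
                t_step += 1
                for k, (holder, name) in enumerate(params):
                    g = grads[k]
                    m[k] = cfg.adam_beta1 * m[k] + (1 - cfg.adam_beta1) * g
                    v[k] = cfg.adam_beta2 * v[k] + (1 - cfg.adam_beta2) * g * g
                    m_hat = m[k] / (1 - cfg.adam_beta1 ** t_step)
                    v_hat = v[k] / (1 - cfg.adam_beta2 ** t_step)
                    setattr(holder, name, getattr(holder, name)
                            - cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.adam_eps))
            probs = self._forward(seq_all)
            loss = self._loss(probs, Y)
            acc = float(np.mean(probs.argmax(axis=1) == Y))
            self.history_.append({"epoch": epoch, "loss": float(loss), "accuracy": acc})
            if loss <= cfg.loss_target:
                break
        return self.history_

    # -- inference --------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.classes_ is None or self.n_features_ is None:
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"feature width {X.shape[1]} does not match model ({self.n_features_})")
        return self._forward(self._to_sequences(self._transform(X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        # np.argmax breaks ties toward the lowest class index.
        return np.asarray(self.classes_)[probs.argmax(axis=1)]

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialise weights, scaler and config to a single JSON file."""
        if self.classes_ is None:
            raise ValueError("cannot save an unfitted model")
        blob = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.cfg).items()},
            "classes": self.classes_,
            "n_features": self.n_features_,
            "feature_mean": self.feature_mean_.tolist(),
            "feature_std": self.feature_std_.tolist(),
            "layers": [
                {name: getattr(layer, name).tolist()
                 for name in GATE_WEIGHT_NAMES + GATE_BIAS_NAMES}
                for layer in self.layers
            ],
            "dense": {"W_d1": self.W_d1.tolist(), "b_d1": self.b_d1.tolist(),
                      "W_d2": self.W_d2.tolist(), "b_d2": self.b_d2.tolist()},
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "StackedLstmClassifier":
        blob = json.loads(Path(path).read_text())
        cfg_dict = dict(blob["config"])
        if cfg_dict.get("sequence_reshape") is not None:
            cfg_dict["sequence_reshape"] = tuple(cfg_dict["sequence_reshape"])
        model = cls(LstmConfig(**cfg_dict))
        model.classes_ = blob["classes"]
        model.n_features_ = blob["n_features"]
        model.feature_mean_ = np.asarray(blob["feature_mean"])
        model.feature_std_ = np.asarray(blob["feature_std"])
        model.layers = [
            LstmCellWeights(**{name: np.asarray(layer[name])
                               for name in GATE_WEIGHT_NAMES + GATE_BIAS_NAMES})
            for layer in blob["layers"]
        ]
        d = blob["dense"]
        model.W_d1 = np.asarray(d["W_d1"])
        model.b_d1 = np.asarray(d["b_d1"])
        model.W_d2 = np.asarray(d["W_d2"])
        model.b_d2 = np.asarray(d["b_d2"])
        return model


def train(features: FeatureSet, cfg: LstmConfig | None = None
          ) -> tuple[StackedLstmClassifier, list[dict]]:
    """Train a stacked-LSTM classifier on a FeatureSet."""
    model = StackedLstmClassifier(cfg)
    history = model.fit(features.X, features.labels)
    return model, history


def predict(model: StackedLstmClassifier, features: FeatureSet) -> np.ndarray:
    """Predicted activity labels, one per feature row."""
    return model.predict(features.X)
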