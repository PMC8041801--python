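"""Sequence models for severity estimation.

The primary model is a bidirectional many-to-many LSTM regressor: a
fully-connected input layer maps the 78-feature window descriptor to the
number of hidden states (ReLU), a bidirectional LSTM stack models the
long-term temporal structure of a round, and a fully-connected ReLU layer
plus a linear output head emit one severity score per 5-s window.  Dropout
is applied after the fully-connected layers and between LSTM layers during
training only.  Training minimizes masked mean-squared error with Adam
(learning rate 1e-3) over padded batches of 32 round sequences for a fixed
number of epochs; before every epoch the order of the activity blocks
within each round is shuffled (windows inside a block keep their order) so
the network cannot memorize the protocol's activity order.

The network, its backpropagation and the Adam optimizer are implemented
directly on NumPy arrays in float64; gradients are exact (verified against
finite differences in the test suite) and training is bit-deterministic
given the seed.

A window-independent ordinary-least-squares linear regressor on the same
standardized features serves as the baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MAIMS_MAX
from .preprocess import RoundSequence

logger = logging.getLogger(__name__)

HIDDEN_GRID = (64, 128, 192, 256, 320)
LAYER_GRID = (1, 2, 3)

__all__ = [
    "ModelConfig",
    "Standardizer",
    "BiLSTMNet",
    "SequenceModel",
    "LinearModel",
    "train_lstm",
    "predict",
    "hyperparam_search",
    "default_grid",
    "full_grid",
    "train_linear",
    "predict_linear",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of one LSTM candidate.

    Defaults follow the training recipe the model was designed with:
    learning rate 1e-3, batches of 32 sequences, dropout 0.7, 150 epochs;
    the layer/hidden grids searched are 1-3 layers x {64, 128, ..., 320}
    hidden states.
    """

    n_hidden: int = 128
    n_layers: int = 3
    dropout: float = 0.7
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers not in LAYER_GRID:
            raise ValueError(f"n_layers must be in {LAYER_GRID}, got {self.n_layers}")
        if self.n_hidden not in HIDDEN_GRID:
            raise ValueError(f"n_hidden must be in {HIDDEN_GRID}, got {self.n_hidden}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on training windows only."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0.0] = 1.0
        self.std = std
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


from scipy.special import expit as _sigmoid


class BiLSTMNet:
    """Bidirectional many-to-many LSTM regressor on padded batches.

    ``forward`` consumes ``X`` of shape (B, T, F) with a {0,1} ``mask`` of
    shape (B, T); padded steps neither emit output nor advance the
    recurrent state (the state is carried through), so a sequence's
    predictions are independent of how much padding the batch carries.

    Both directions of a layer are advanced by a single fused recurrence:
    the backward direction sees the time-reversed input (with its reversed
    mask, so the carry logic handles the leading padding), the two
    directions' recurrent weights form a block-diagonal matrix, and the
    gate nonlinearities are applied across a (B, 2, 4H) view.  Training
    arrays default to float32; float64 is used by the finite-difference
    gradient checks.
    """

    def __init__(
        self,
        n_features: int,
        n_hidden: int,
        n_layers: int,
        dropout: float,
        rng: np.random.Generator,
        output_bias: float = 0.0,
        dtype=np.float32,
    ) -> None:
        self.n_features = n_features
        self.H = n_hidden
        self.L = n_layers
        self.dropout = dropout
        self.dtype = np.dtype(dtype)
        p: dict[str, np.ndarray] = {}

        def uni(shape, fan_in):
            k = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-k, k, size=shape).astype(self.dtype)

        p["W_in"] = uni((n_features, self.H), n_features)
        p["b_in"] = np.zeros(self.H, dtype=self.dtype)
        for layer in range(self.L):
            d_in = self.H if layer == 0 else 2 * self.H
            for direction in ("f", "b"):
                p[f"Wx_{layer}_{direction}"] = uni((d_in, 4 * self.H), d_in)
                p[f"Wh_{layer}_{direction}"] = uni((self.H, 4 * self.H), self.H)
                b = np.zeros(4 * self.H, dtype=self.dtype)
                b[self.H : 2 * self.H] = 1.0  # forget-gate bias
                p[f"b_{layer}_{direction}"] = b
        p["W_fc"] = uni((2 * self.H, self.H), 2 * self.H)
        p["b_fc"] = np.zeros(self.H, dtype=self.dtype)
        p["W_out"] = uni((self.H, 1), self.H)
        p["b_out"] = np.array([output_bias], dtype=self.dtype)
        self.params = p
        self._adam_m: dict[str, np.ndarray] = {}
        self._adam_v: dict[str, np.ndarray] = {}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def _dropout_mask(self, shape, train: bool, rng: np.random.Generator | None):
        if not train or self.dropout == 0.0:
            return None
        keep = 1.0 - self.dropout
        return ((rng.random(shape) < keep) / keep).astype(self.dtype)

    def _block_wh(self, layer):
        """(2H, 8H) block-diagonal recurrent weights for the fused recurrence."""
        H = self.H
        Whb = np.zeros((2 * H, 8 * H), dtype=self.dtype)
        Whb[:H, : 4 * H] = self.params[f"Wh_{layer}_f"]
        Whb[H:, 4 * H :] = self.params[f"Wh_{layer}_b"]
        return Whb

    def _bilstm_layer(self, X, mask, layer):
        """One bidirectional layer; returns ((B,T,2H) outputs, cache).

        Loop-time index t holds original time t for the forward direction
        and original time T-1-t for the backward direction.
        """
        p = self.params
        B, T, _ = X.shape
        H = self.H
        Xrev = X[:, ::-1]
        ZX = np.empty((B, T, 2, 4 * H), dtype=self.dtype)
        ZX[:, :, 0] = X @ p[f"Wx_{layer}_f"] + p[f"b_{layer}_f"]
        ZX[:, :, 1] = Xrev @ p[f"Wx_{layer}_b"] + p[f"b_{layer}_b"]
        Ms = np.stack([mask, mask[:, ::-1]], axis=2)  # (B, T, 2)
        Whb = self._block_wh(layer)
        h = np.zeros((B, 2 * H), dtype=self.dtype)
        c = np.zeros((B, 2, H), dtype=self.dtype)
        out = np.zeros((B, T, 2, H), dtype=self.dtype)
        Hprev = np.zeros((B, T, 2, H), dtype=self.dtype)
        Cprev = np.zeros((B, T, 2, H), dtype=self.dtype)
        gates = np.zeros((B, T, 2, 4 * H), dtype=self.dtype)  # i,f,g,o post-nonlinearity
        TC = np.zeros((B, T, 2, H), dtype=self.dtype)
        for t in range(T):
            z = ZX[:, t] + (h @ Whb).reshape(B, 2, 4 * H)
            i = _sigmoid(z[..., :H])
            f = _sigmoid(z[..., H : 2 * H])
            g = np.tanh(z[..., 2 * H : 3 * H])
            o = _sigmoid(z[..., 3 * H :])
            hp = h.reshape(B, 2, H)
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = Ms[:, t][..., None]  # (B, 2, 1)
            out[:, t] = m * h_new
            Hprev[:, t] = hp
            Cprev[:, t] = c
            gates[:, t, :, :H] = i
            gates[:, t, :, H : 2 * H] = f
            gates[:, t, :, 2 * H : 3 * H] = g
            gates[:, t, :, 3 * H :] = o
            TC[:, t] = tc
            h = (m * h_new + (1.0 - m) * hp).reshape(B, 2 * H)
            c = m * c_new + (1.0 - m) * c
        # un-reverse the backward direction's outputs to original time
        y = np.concatenate([out[:, :, 0], out[:, ::-1, 1]], axis=2)
        return y, {"Hprev": Hprev, "Cprev": Cprev, "gates": gates, "TC": TC,
                   "Ms": Ms}

    def forward(self, X, mask, train: bool = False, rng: np.random.Generator | None = None):
        """Predict one score per step; returns (pred (B,T), cache)."""
        p = self.params
        X = np.asarray(X, dtype=self.dtype)
        mask = np.asarray(mask, dtype=self.dtype)
        B, T, _ = X.shape
        cache: dict = {"X": X, "mask": mask, "drop": {}}
        a_in = X @ p["W_in"] + p["b_in"]
        h0 = np.maximum(a_in, 0.0)
        d0 = self._dropout_mask(h0.shape, train, rng)
        cache["h0"] = h0
        cache["drop"]["in"] = d0
        cur = h0 if d0 is None else h0 * d0
        cache["layer_in"] = []
        cache["layer_steps"] = []
        for layer in range(self.L):
            cache["layer_in"].append(cur)
            y, lcache = self._bilstm_layer(cur, mask, layer)
            cache["layer_steps"].append(lcache)
            if layer < self.L - 1:
                d = self._dropout_mask(y.shape, train, rng)
                cache["drop"][f"layer_{layer}"] = d
                cur = y if d is None else y * d
            else:
                cur = y
        cache["lstm_out"] = cur
        a_fc = cur @ p["W_fc"] + p["b_fc"]
        fc = np.maximum(a_fc, 0.0)
        dfc = self._dropout_mask(fc.shape, train, rng)
        cache["fc"] = fc
        cache["drop"]["fc"] = dfc
        fc_d = fc if dfc is None else fc * dfc
        cache["fc_d"] = fc_d
        pred = (fc_d @ p["W_out"] + p["b_out"])[..., 0]
        return pred, cache

    # -- backward ----------------------------------------------------------

    def _bilstm_layer_backward(self, dY, lcache, layer, X_layer):
        """Backprop one fused bidirectional layer.

        ``dY`` is (B,T,2H) in original time.  Gate gradients are accumulated
        into a (B,T,2,4H) buffer so every weight gradient reduces to one
        matmul at the end.  Returns (dX, grads-dict-fragment).
        """
        p = self.params
        H = self.H
        B, T = dY.shape[:2]
        Hprev, Cprev = lcache["Hprev"], lcache["Cprev"]
        gates, TC, Ms = lcache["gates"], lcache["TC"], lcache["Ms"]
        # stack into loop time: forward half as-is, backward half reversed
        dOuts = np.stack([dY[:, :, :H], dY[:, ::-1, H:]], axis=2)  # (B,T,2,H)
        WhbT = self._block_wh(layer).T  # (8H, 2H)
        dZ = np.zeros((B, T, 2, 4 * H), dtype=self.dtype)
        dh = np.zeros((B, 2, H), dtype=self.dtype)
        dc = np.zeros((B, 2, H), dtype=self.dtype)
        for t in range(T - 1, -1, -1):
            m = Ms[:, t][..., None]
            i = gates[:, t, :, :H]
            f = gates[:, t, :, H : 2 * H]
            g = gates[:, t, :, 2 * H : 3 * H]
            o = gates[:, t, :, 3 * H :]
            tc = TC[:, t]
            dh_new = m * (dOuts[:, t] + dh)
            dc_new = m * dc + dh_new * o * (1.0 - tc * tc)
            dzt = dZ[:, t]
            dzt[..., :H] = (dc_new * g) * i * (1.0 - i)
            dzt[..., H : 2 * H] = (dc_new * Cprev[:, t]) * f * (1.0 - f)
            dzt[..., 2 * H : 3 * H] = (dc_new * i) * (1.0 - g * g)
            dzt[..., 3 * H :] = (dh_new * tc) * o * (1.0 - o)
            dh = (dzt.reshape(B, 8 * H) @ WhbT).reshape(B, 2, H) + (1.0 - m) * dh
            dc = dc_new * f + (1.0 - m) * dc
        D = X_layer.shape[2]
        Xf = X_layer.reshape(-1, D)
        Xb = np.ascontiguousarray(X_layer[:, ::-1]).reshape(-1, D)
        Zf = np.ascontiguousarray(dZ[:, :, 0]).reshape(-1, 4 * H)
        Zb = np.ascontiguousarray(dZ[:, :, 1]).reshape(-1, 4 * H)
        grads = {
            f"Wx_{layer}_f": Xf.T @ Zf,
            f"Wx_{layer}_b": Xb.T @ Zb,
            f"Wh_{layer}_f": np.ascontiguousarray(Hprev[:, :, 0]).reshape(-1, H).T @ Zf,
            f"Wh_{layer}_b": np.ascontiguousarray(Hprev[:, :, 1]).reshape(-1, H).T @ Zb,
            f"b_{layer}_f": Zf.sum(axis=0),
            f"b_{layer}_b": Zb.sum(axis=0),
        }
        dX = Zf.reshape(B, T, 4 * H) @ p[f"Wx_{layer}_f"].T
        dX += (Zb.reshape(B, T, 4 * H) @ p[f"Wx_{layer}_b"].T)[:, ::-1]
        return dX, grads

    def backward(self, cache, dpred):
        """Gradients of a scalar loss wrt all parameters, given dL/dpred (B,T)."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        fc_d = cache["fc_d"]
        B, T, _ = fc_d.shape
        dpred3 = np.asarray(dpred, dtype=self.dtype)[..., None]  # (B,T,1)
        grads["W_out"] = fc_d.reshape(-1, self.H).T @ dpred3.reshape(-1, 1)
        grads["b_out"] = dpred3.sum(axis=(0, 1))
        dfc_d = dpred3 @ p["W_out"].T
        dfc = dfc_d if cache["drop"]["fc"] is None else dfc_d * cache["drop"]["fc"]
        dfc = dfc * (cache["fc"] > 0)
        lstm_out = cache["lstm_out"]
        grads["W_fc"] = lstm_out.reshape(-1, 2 * self.H).T @ dfc.reshape(-1, self.H)
        grads["b_fc"] = dfc.sum(axis=(0, 1))
        dY = dfc @ p["W_fc"].T  # (B,T,2H)
        for layer in range(self.L - 1, -1, -1):
            if layer < self.L - 1:
                d = cache["drop"].get(f"layer_{layer}")
                if d is not None:
                    dY = dY * d
            dY, layer_grads = self._bilstm_layer_backward(
                dY, cache["layer_steps"][layer], layer, cache["layer_in"][layer]
            )
            grads.update(layer_grads)
        d0 = cache["drop"]["in"]
        dh0 = dY if d0 is None else dY * d0
        dh0 = dh0 * (cache["h0"] > 0)
        X = cache["X"]
        grads["W_in"] = X.reshape(-1, self.n_features).T @ dh0.reshape(-1, self.H)
        grads["b_in"] = dh0.sum(axis=(0, 1))
        return grads

    # -- optimizer ---------------------------------------------------------

    def adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            g = g.reshape(self.params[k].shape)
            m = self._adam_m.setdefault(k, np.zeros_like(self.params[k]))
            v = self._adam_v.setdefault(k, np.zeros_like(self.params[k]))
            m += (1 - beta1) * (g - m)
            v += (1 - beta2) * (g * g - v)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class SequenceModel:
    """A trained biLSTM together with its feature standardization."""

    net: BiLSTMNet
    config: ModelConfig
    standardizer: Standardizer
    loss_history: list[float] = field(default_factory=list)


def _pad_batch(feats: list[np.ndarray], golds: list[np.ndarray]):
    B = len(feats)
    T = max(f.shape[0] for f in feats)
    F = feats[0].shape[1]
    X = np.zeros((B, T, F))
    Y = np.zeros((B, T))
    M = np.zeros((B, T))
    for b, (f, y) in enumerate(zip(feats, golds)):
        X[b, : f.shape[0]] = f
        Y[b, : y.size] = y
        M[b, : y.size] = 1.0
    return X, Y, M


def train_lstm(
    train_rounds: list[RoundSequence],
    config: ModelConfig,
    standardizer: Standardizer | None = None,
) -> SequenceModel:
    """Train the biLSTM on featurized round sequences.

    Feature standardization statistics are fitted on the training windows
    (unless a pre-fitted :class:`Standardizer` is supplied) and stored in
    the returned model.  The output bias is initialized at the training-
    target mean so the loss starts near the target variance.
    """
    rounds = []
    for seq in train_rounds:
        if seq.features is None:
            raise ValueError("rounds must be featurized before training")
        if seq.n_windows == 0:
            warnings.warn(
                f"round {seq.subject_id}/{seq.round_index} has zero windows; skipped",
                stacklevel=2,
            )
            continue
        rounds.append(seq)
    if len(rounds) < 2:
        raise ValueError("need at least 2 non-empty training rounds")
    all_X = np.vstack([s.features for s in rounds])
    if standardizer is None:
        standardizer = Standardizer().fit(all_X)
    n_features = all_X.shape[1]
    y_mean = float(np.mean(np.concatenate([s.gold for s in rounds])))

    rng = np.random.default_rng(config.seed)
    net = BiLSTMNet(
        n_features, config.n_hidden, config.n_layers, config.dropout, rng,
        output_bias=y_mean,
    )
    std_feats = [standardizer.transform(s.features) for s in rounds]

    history: list[float] = []
    n = len(rounds)
    for _epoch in range(config.epochs):
        shuffled = []
        for seq, sf in zip(rounds, std_feats):
            blocks = seq.activity_blocks()
            order = np.concatenate([blocks[i] for i in rng.permutation(len(blocks))])
            shuffled.append((sf[order], seq.gold[order]))
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_count = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            feats = [shuffled[i][0] for i in idx]
            golds = [shuffled[i][1] for i in idx]
            X, Y, M = _pad_batch(feats, golds)
            pred, cache = net.forward(X, M, train=True, rng=rng)
            n_valid = M.sum()
            resid = (pred - Y) * M
            loss = float((resid**2).sum() / n_valid)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {_epoch}; "
                    f"config={config}, batch rounds={idx.tolist()}"
                )
            dpred = 2.0 * resid / n_valid
            grads = net.backward(cache, dpred)
            net.adam_step(grads, config.learning_rate)
            epoch_loss += loss * n_valid
            epoch_count += n_valid
        history.append(epoch_loss / epoch_count)
    return SequenceModel(net=net, config=config, standardizer=standardizer,
                         loss_history=history)


def predict(model: SequenceModel, round_seq: RoundSequence) -> np.ndarray:
    """One severity score per window of the round, clipped to [0, 28]."""
    if round_seq.features is None:
        raise ValueError("round must be featurized")
    if round_seq.n_windows == 0:
        return np.zeros(0)
    if round_seq.features.shape[1] != model.net.n_features:
        raise ValueError(
            f"feature length {round_seq.features.shape[1]} != model's "
            f"{model.net.n_features}"
        )
    X = model.standardizer.transform(round_seq.features)[None]
    M = np.ones(X.shape[:2])
    pred, _ = model.net.forward(X, M, train=False)
    return np.clip(pred[0], 0.0, MAIMS_MAX)


def default_grid() -> list[tuple[int, int]]:
    """The reduced 2-point (n_layers, n_hidden) grid used for routine runs."""
    return [(1, 64), (2, 64)]


def full_grid() -> list[tuple[int, int]]:
    """The full 15-point search grid: 3 layer counts x 5 hidden sizes."""
    return [(nl, nh) for nl in LAYER_GRID for nh in HIDDEN_GRID]


def hyperparam_search(
    train_rounds: list[RoundSequence],
    grid: list[tuple[int, int]] | None = None,
    seed: int = 0,
    base: ModelConfig | None = None,
) -> ModelConfig:
    """Select (n_layers, n_hidden) by validation Pearson r.

    20% of the training rounds (whole rounds, never split) are held out as
    the validation set; every grid point is trained on the remainder and the
    configuration with maximum pooled window-level validation r wins.  Exact
    ties go to the smaller model (fewer layers, then fewer hidden states).
    """
    from scipy import stats

    if grid is None:
        grid = full_grid()
    base = base if base is not None else ModelConfig()
    rounds = [s for s in train_rounds if s.n_windows > 0]
    if len(rounds) < 5:
        raise ValueError("hyper-parameter search requires at least 5 training rounds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rounds))
    n_val = max(1, round(0.2 * len(rounds)))
    val = [rounds[i] for i in order[:n_val]]
    train = [rounds[i] for i in order[n_val:]]
    if not train:
        raise ValueError("validation split left no training rounds")

    results = []
    for n_layers, n_hidden in grid:
        cfg = ModelConfig(
            n_hidden=n_hidden, n_layers=n_layers, dropout=base.dropout,
            learning_rate=base.learning_rate, batch_size=base.batch_size,
            epochs=base.epochs, seed=base.seed,
        )
        model = train_lstm(train, cfg)
        preds = np.concatenate([predict(model, s) for s in val])
        gold = np.concatenate([s.gold for s in val])
        if np.std(gold) == 0.0 or np.std(preds) == 0.0:
            r = -np.inf
        else:
            r = float(stats.pearsonr(preds, gold)[0])
        logger.info("grid point layers=%d hidden=%d: val r=%.4f", n_layers, n_hidden, r)
        results.append((r, n_layers, n_hidden, cfg))
    results.sort(key=lambda t: (-t[0], t[1], t[2]))
    return results[0][3]


# ---------------------------------------------------------------------------
# linear-regression baseline


@dataclass
class LinearModel:
    """OLS weights mapping one standardized 78-vector to one severity score."""

    coef: np.ndarray
    intercept: float
    standardizer: Standardizer


def train_linear(X: np.ndarray, y: np.ndarray,
                 standardizer: Standardizer | None = None) -> LinearModel:
    """Ordinary least squares on window features; ridge (1e-6) fallback when
    the design is rank-deficient."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if standardizer is None:
        standardizer = Standardizer().fit(X)
    Z = standardizer.transform(X)
    A = np.hstack([Z, np.ones((Z.shape[0], 1))])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {A.shape[1]}); "
            "falling back to ridge with penalty 1e-6",
            stacklevel=2,
        )
        lam = 1e-6
        beta = np.linalg.solve(A.T @ A + lam * np.eye(A.shape[1]), A.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearModel(coef=beta[:-1], intercept=float(beta[-1]),
                       standardizer=standardizer)


def predict_linear(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Per-window scores from the linear baseline, clipped to [0, 28]."""
    Z = model.standardizer.transform(np.asarray(X, dtype=float))
    return np.clip(Z @ model.coef + model.intercept, 0.0, MAIMS_MAX)
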