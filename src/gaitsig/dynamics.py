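"""Recurrent gait dynamics model: an LSTM one-step-ahead predictor.

The model is a single LSTM layer with a linear readout, trained
sequence-to-sequence with teacher forcing to predict the next sample of the
(per-channel standardized) multi-joint gait time series.  Training uses Adam
on full batches (all trials at once), dropout on the hidden-state path to the
readout only, and an L2 penalty on the LSTM input kernel.  The per-time-step
hidden states are the latent gait dynamics from which signatures are built.

The LSTM forward pass, backpropagation through time, and the Adam optimizer
are implemented directly on NumPy arrays in float64, which keeps training
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class RNNConfig:
    """Dynamics-model hyperparameters.

    Defaults follow the reference configuration (512 LSTM units, Adam with
    learning rate 1e-4, 20% dropout after the hidden layer, L2 kernel
    regularization 0.01).  Small desk-scale models typically use fewer units
    and a larger learning rate.
    """

    hidden_units: int = 512
    learning_rate: float = 1e-4
    dropout_rate: float = 0.2
    l2_strength: float = 0.01
    epochs: int = 500
    batch_mode: str = "per_trial"
    seed: int = 0
    early_stopping_patience: int = 25
    early_stopping_tol: float = 1e-5
    grad_clip: float = 5.0
    include_cell_state: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class DynamicsModel:
    """Trained LSTM one-step predictor with its standardization statistics."""

    config: RNNConfig
    W: np.ndarray  # input kernel (C, 4H), gate order i|f|g|o
    U: np.ndarray  # recurrent kernel (H, 4H)
    b: np.ndarray  # gate bias (4H,)
    V: np.ndarray  # readout weights (H, C)
    d: np.ndarray  # readout bias (C,)
    channel_mean: np.ndarray  # (C,)
    channel_std: np.ndarray  # (C,)
    history: list = field(default_factory=list)  # per-epoch training loss
    trained: bool = False

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def hidden_units(self) -> int:
        return self.U.shape[0]

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.channel_mean) / self.channel_std

    def unstandardize(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.channel_std + self.channel_mean


@dataclass
class LatentStates:
    """Per-time-step internal activations of the dynamics model (T' x H)."""

    trial_id: str
    states: np.ndarray
    which_state: str = "hidden"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _init_params(n_channels: int, h: int, rng: np.random.Generator):
    """Glorot-uniform input/readout kernels, orthogonal recurrent kernel,
    forget-gate bias 1."""
    lim_w = np.sqrt(6.0 / (n_channels + 4 * h))
    W = rng.uniform(-lim_w, lim_w, size=(n_channels, 4 * h))
    U = np.zeros((h, 4 * h))
    for k in range(4):
        a = rng.standard_normal((h, h))
        q, r = np.linalg.qr(a)
        U[:, k * h:(k + 1) * h] = q * np.sign(np.diag(r))
    b = np.zeros(4 * h)
    b[h:2 * h] = 1.0
    lim_v = np.sqrt(6.0 / (h + n_channels))
    V = rng.uniform(-lim_v, lim_v, size=(h, n_channels))
    d = np.zeros(n_channels)
    return W, U, b, V, d


def _forward(X, W, U, b, return_cache: bool):
    """LSTM forward over (B, T, C) inputs; returns hidden states (T, B, H).

    With ``return_cache`` the per-step gate activations and cell states are
    kept for backpropagation through time.
    """
    B, T, _ = X.shape
    H = U.shape[0]
    h_t = np.zeros((B, H))
    c_t = np.zeros((B, H))
    Hs = np.empty((T, B, H))
    cache = None
    if return_cache:
        cache = {
            "i": np.empty((T, B, H)), "f": np.empty((T, B, H)),
            "g": np.empty((T, B, H)), "o": np.empty((T, B, H)),
            "hc": np.empty((T, B, H)), "c": np.empty((T, B, H)),
        }
    xw = X @ W  # (B, T, 4H), precomputed input contribution
    for t in range(T):
        z = xw[:, t, :] + h_t @ U + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_t = f * c_t + i * g
        hc = np.tanh(c_t)
        h_t = o * hc
        Hs[t] = h_t
        if return_cache:
            cache["i"][t] = i
            cache["f"][t] = f
            cache["g"][t] = g
            cache["o"][t] = o
            cache["hc"][t] = hc
            cache["c"][t] = c_t
    return Hs, cache


def _backward(X, Hs, cache, dH, W, U):
    """BPTT given upstream hidden-state gradients dH (T, B, H)."""
    B, T, C = X.shape
    H = U.shape[0]
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(4 * H)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    Ut = U.T
    dz = np.empty((B, 4 * H))
    for t in range(T - 1, -1, -1):
        i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
        hc = cache["hc"][t]
        c_prev = cache["c"][t - 1] if t > 0 else np.zeros((B, H))
        h_prev = Hs[t - 1] if t > 0 else np.zeros((B, H))
        dh = dH[t] + dh_next
        dc = dc_next + dh * o * (1.0 - hc * hc)
        dz[:, :H] = dc * g * i * (1.0 - i)
        dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
        dz[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
        dz[:, 3 * H:] = dh * hc * o * (1.0 - o)
        dW += X[:, t, :].T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh_next = dz @ Ut
        dc_next = dc * f
    return dW, dU, db


def _global_norm_clip(grads: list[np.ndarray], max_norm: float) -> None:
    if max_norm <= 0:
        return
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > max_norm:
        scale = max_norm / total
        for g in grads:
            g *= scale


def train_dynamics_model(
    trials: list[np.ndarray],
    config: RNNConfig,
    verbose: bool = False,
) -> DynamicsModel:
    """Train the LSTM one-step predictor on a list of (T, C) trial matrices.

    Channels are standardized with cohort-wide mean/SD (stored with the
    model).  All trials are trained jointly in one batch per epoch, matching
    the batched-by-trial-count protocol.  Early stopping monitors the
    training loss plateau.  Raises on non-finite loss or mismatched channel
    counts.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    C = trials[0].shape[1]
    for k, tr in enumerate(trials):
        if tr.ndim != 2 or tr.shape[1] != C:
            raise ValueError(
                f"trial {k} has shape {tr.shape}; all trials must be (T, {C})"
            )
    T = min(tr.shape[0] for tr in trials)
    stack = np.stack([np.asarray(tr[:T], dtype=float) for tr in trials])  # (B,T,C)

    flat = stack.reshape(-1, C)
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    std = np.where(std < 1e-8, 1.0, std)
    Xfull = (stack - mean) / std
    X = Xfull[:, :-1, :]
    Y = Xfull[:, 1:, :]
    B, Tm, _ = X.shape

    rng = np.random.default_rng(config.seed)
    H = config.hidden_units
    W, U, b, V, d = _init_params(C, H, rng)

    params = [W, U, b, V, d]
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    keep = 1.0 - config.dropout_rate

    history: list[float] = []
    best = np.inf
    stale = 0
    denom = B * Tm * C
    for epoch in range(config.epochs):
        Hs, cache = _forward(X, W, U, b, return_cache=True)
        if config.dropout_rate > 0:
            mask = (rng.random((Tm, B, H)) < keep).astype(float) / keep
            Hd = Hs * mask
        else:
            mask = None
            Hd = Hs
        pred = Hd @ V + d  # (T, B, C)
        err = pred - np.transpose(Y, (1, 0, 2))
        mse = float(np.mean(err * err))
        loss = mse + config.l2_strength * float(np.sum(W * W))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch}: mse={mse}; "
                "reduce the learning rate or check the input scaling"
            )
        history.append(loss)

        dpred = (2.0 / denom) * err  # (T, B, C)
        dV = np.tensordot(Hd, dpred, axes=([0, 1], [0, 1]))
        dd = dpred.sum(axis=(0, 1))
        dH = dpred @ V.T
        if mask is not None:
            dH = dH * mask
        dW, dU, db = _backward(X, Hs, cache, dH, W, U)
        dW += 2.0 * config.l2_strength * W
        grads = [dW, dU, db, dV, dd]
        _global_norm_clip(grads, config.grad_clip)

        t_adam = epoch + 1
        bc1 = 1.0 - beta1 ** t_adam
        bc2 = 1.0 - beta2 ** t_adam
        for p, g, m_, v_ in zip(params, grads, m_adam, v_adam):
            m_ *= beta1
            m_ += (1.0 - beta1) * g
            v_ *= beta2
            v_ += (1.0 - beta2) * g * g
            p -= lr * (m_ / bc1) / (np.sqrt(v_ / bc2) + eps)

        if verbose and (epoch % 10 == 0 or epoch == config.epochs - 1):
            print(f"epoch {epoch:4d}  loss {loss:.6f}")
        if loss < best - config.early_stopping_tol:
            best = loss
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stopping_patience:
                break

    return DynamicsModel(
        config=config, W=W, U=U, b=b, V=V, d=d,
        channel_mean=mean, channel_std=std,
        history=history, trained=True,
    )


def _check_sequence(model: DynamicsModel, sequence: np.ndarray) -> np.ndarray:
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 2 or seq.shape[0] < 2:
        raise ValueError("sequence must be (T, C) with T >= 2")
    if seq.shape[1] != model.n_channels:
        raise ValueError(
            f"sequence has {seq.shape[1]} channels, model expects "
            f"{model.n_channels}"
        )
    return seq


def predict_one_step(model: DynamicsModel, sequence: np.ndarray,
                     standardized: bool = False) -> np.ndarray:
    """One-step-ahead predictions: row t estimates input row t+1.

    Inference is deterministic (dropout disabled).  Returns (T-1, C) in
    original channel units unless ``standardized``.
    """
    seq = _check_sequence(model, sequence)
    Xs = model.standardize(seq)[None, :-1, :]
    Hs, _ = _forward(Xs, model.W, model.U, model.b, return_cache=False)
    pred = Hs[:, 0, :] @ model.V + model.d
    return pred if standardized else model.unstandardize(pred)


def extract_latent_states(model: DynamicsModel, sequence: np.ndarray,
                          trial_id: str = "") -> LatentStates:
    """Hidden-state trajectory h_t for every prediction step, dropout off.

    Returns (T-1, H) states aligned with the one-step predictions; with
    ``config.include_cell_state`` the cell state is concatenated to (T-1, 2H).
    """
    if not model.trained:
        raise ValueError("model is untrained; call train_dynamics_model first")
    seq = _check_sequence(model, sequence)
    Xs = model.standardize(seq)[None, :-1, :]
    Hs, cache = _forward(Xs, model.W, model.U, model.b, return_cache=True)
    states = Hs[:, 0, :]
    if model.config.include_cell_state:
        states = np.concatenate([states, cache["c"][:, 0, :]], axis=1)
    return LatentStates(trial_id=trial_id, states=states, which_state="hidden")


def one_step_r2(model: DynamicsModel, sequence: np.ndarray) -> np.ndarray:
    """Per-channel R^2 of the one-step prediction against the shifted input."""
    seq = _check_sequence(model, sequence)
    target = model.standardize(seq)[1:]
    pred = predict_one_step(model, seq, standardized=True)
    sse = np.sum((pred - target) ** 2, axis=0)
    sst = np.sum((target - target.mean(axis=0)) ** 2, axis=0)
    sst = np.where(sst < 1e-12, 1.0, sst)
    return 1.0 - sse / sst
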