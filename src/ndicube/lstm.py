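"""Per-cluster recurrent gap filling with a compact NumPy LSTM.

One sequence-to-one LSTM (single hidden layer, linear head) is trained per
cluster on the cluster's most complete pixel, then applied to every member.
Training preserves chronology — windows are never shuffled and the
validation split is the chronological tail — because the network learns the
temporal relationships between samples. Optimisation is Adam on an MSE
loss with early stopping on the validation loss (best weights restored).

Prediction uses a hybrid input strategy, in priority order per date:
observed value (scaled), the model's own earlier prediction for that date,
and finally linear interpolation between the nearest valid neighbours. The
network therefore always sees a complete input window built from the most
reliable information available.

The forecast-error scale sigma_LSTM per pixel is the standard deviation of
(prediction - observation) over the pixel's valid dates, pooled at cluster
level when a pixel has too few residual pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import MinMaxScaler

from .cube import GapCube
from .clustering import ClusterAssignment

__all__ = [
    "LSTMConfig",
    "LSTMNetwork",
    "WindowSet",
    "make_windows",
    "train_cluster_model",
    "predict_hybrid",
    "estimate_sigma_lstm",
    "impute_lstm",
    "linear_interpolate",
    "PROV_OBSERVED",
    "PROV_RECYCLED",
    "PROV_FALLBACK",
]

# Provenance codes for the input element used at each date.
PROV_OBSERVED = 0
PROV_RECYCLED = 1
PROV_FALLBACK = 2


@dataclass(frozen=True)
class LSTMConfig:
    """Hyperparameters of the per-cluster sequence model.

    Defaults follow the operational configuration: 32 hidden units, Adam at
    learning rate 0.005, batches of 32, at most 128 epochs limited by early
    stopping with patience 5 on the validation MSE, min-max input scaling
    to [0, 1]. The input window (12 steps = 60 days) and the chronological
    validation fraction (0.2) are package choices.
    """

    layer_size: int = 32
    batch_size: int = 32
    learning_rate: float = 0.005
    max_epochs: int = 128
    patience: int = 5
    window: int = 12
    val_fraction: float = 0.2
    min_residuals: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


def linear_interpolate(series: np.ndarray) -> np.ndarray:
    """Linearly interpolate interior gaps; extend nearest values at the ends.

    The 'simplest interpolation' fallback of the hybrid input strategy.
    Raises if the series has no valid value at all.
    """
    series = np.asarray(series, dtype=float)
    valid = np.isfinite(series)
    if not valid.any():
        raise ValueError("cannot interpolate a fully missing series")
    idx = np.arange(series.size)
    return np.interp(idx, idx[valid], series[valid])


@dataclass
class WindowSet:
    """Chronologically ordered (window, next-value) pairs with a tail split."""

    X_train: np.ndarray  # (n_train, window)
    y_train: np.ndarray
    X_val: np.ndarray  # (n_val, window)
    y_val: np.ndarray
    train_targets: np.ndarray  # time indices of training targets
    val_targets: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.train_targets) + len(self.val_targets)


def make_windows(series: np.ndarray, window: int, val_fraction: float = 0.2) -> WindowSet:
    """Slice a gap-free scaled series into ordered next-step pairs.

    Produces exactly ``T - window`` pairs; the last ``val_fraction`` of
    targets form the validation split, so every validation target is later
    than every training target (no leakage).
    """
    series = np.asarray(series, dtype=float)
    T = series.size
    if T <= window:
        raise ValueError(f"series length {T} must exceed window {window}")
    n = T - window
    X = np.lib.stride_tricks.sliding_window_view(series, window)[:n]
    y = series[window:]
    targets = np.arange(window, T)
    n_val = max(1, int(round(val_fraction * n)))
    n_val = min(n_val, n - 1)  # keep at least one training pair
    split = n - n_val
    return WindowSet(
        X_train=X[:split].copy(),
        y_train=y[:split].copy(),
        X_val=X[split:].copy(),
        y_val=y[split:].copy(),
        train_targets=targets[:split],
        val_targets=targets[split:],
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class LSTMNetwork:
    """Single-layer LSTM with a linear head, trained by full BPTT + Adam.

    Univariate sequence-to-one: input is a scaled window of length W, output
    the scaled next value. Weights follow the usual gate stacking
    [input, forget, cell, output]; the forget-gate bias starts at 1 so early
    training does not wash out the cell state.
    """

    def __init__(self, hidden: int = 32, seed: int = 0) -> None:
        self.hidden = hidden
        rng = np.random.default_rng(seed)
        H = hidden
        k = 1.0 / np.sqrt(H)
        self.Wx = rng.uniform(-k, k, size=(1, 4 * H))
        self.Wh = rng.uniform(-k, k, size=(H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget gate
        self.Wy = rng.uniform(-k, k, size=(H, 1))
        self.by = np.zeros(1)

    # -- parameter plumbing ------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in (self.Wx, self.Wh, self.b, self.Wy, self.by)]

    def set_weights(self, ws: list[np.ndarray]) -> None:
        self.Wx, self.Wh, self.b, self.Wy, self.by = [w.copy() for w in ws]

    # -- forward -----------------------------------------------------------
    def _forward(self, X: np.ndarray, cache: bool = False):
        """X: (B, W) -> predictions (B,); optionally keep the BPTT cache."""
        B, W = X.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        caches = []
        for t in range(W):
            x_t = X[:, t : t + 1]
            z = x_t @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if cache:
                caches.append((x_t, h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        y = (h @ self.Wy + self.by).ravel()
        if cache:
            return y, h, caches
        return y

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        pred = self.predict(X)
        return float(np.mean((pred - y) ** 2))

    # -- backward ----------------------------------------------------------
    def _gradients(self, X: np.ndarray, y: np.ndarray):
        """MSE gradients for one batch via backpropagation through time."""
        B, W = X.shape
        H = self.hidden
        pred, h_last, caches = self._forward(X, cache=True)
        dy = (2.0 / B) * (pred - y)[:, None]  # (B, 1)

        gWx = np.zeros_like(self.Wx)
        gWh = np.zeros_like(self.Wh)
        gb = np.zeros_like(self.b)
        gWy = h_last.T @ dy
        gby = dy.sum(axis=0)

        dh = dy @ self.Wy.T  # (B, H)
        dc = np.zeros((B, H))
        for t in range(W - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            gWx += x_t.T @ dz
            gWh += h_prev.T @ dz
            gb += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        loss = float(np.mean((pred - y) ** 2))
        return loss, [gWx, gWh, gb, gWy, gby]


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def train_cluster_model(
    series_scaled: np.ndarray,
    config: LSTMConfig,
) -> tuple[LSTMNetwork, TrainingHistory]:
    """Train one cluster's model on its (scaled, gap-bridged) reference series.

    Chronological batching without shuffling; Adam updates; training stops
    at ``max_epochs`` or once the validation loss has not improved for
    ``patience`` consecutive epochs, and the best-validation weights are
    restored. Fixed seed gives a reproducible loss history.
    """
    series_scaled = np.asarray(series_scaled, dtype=float)
    if np.nanstd(series_scaled) == 0.0:
        raise ValueError("degenerate (constant) series cannot train a sequence model")
    ws = make_windows(series_scaled, config.window, config.val_fraction)
    net = LSTMNetwork(hidden=config.layer_size, seed=config.seed)

    params = [net.Wx, net.Wh, net.b, net.Wy, net.by]
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history = TrainingHistory()
    best_val = np.inf
    best_weights = net.get_weights()
    stale = 0

    n_train = ws.X_train.shape[0]
    for epoch in range(config.max_epochs):
        epoch_losses = []
        for start in range(0, n_train, config.batch_size):
            Xb = ws.X_train[start : start + config.batch_size]
            yb = ws.y_train[start : start + config.batch_size]
            loss, grads = net._gradients(Xb, yb)
            epoch_losses.append(loss)
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for p, gr, m, v in zip(params, grads, m_state, v_state):
                m *= beta1
                m += (1 - beta1) * gr
                v *= beta2
                v += (1 - beta2) * gr**2
                p -= lr_t * m / (np.sqrt(v) + eps)
        val = net.loss(ws.X_val, ws.y_val)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val)
        if val < best_val - 1e-12:
            best_val = val
            best_weights = net.get_weights()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                history.stopped_epoch = epoch
                break
    else:
        history.stopped_epoch = config.max_epochs - 1
    net.set_weights(best_weights)
    return net, history


@dataclass
class PixelImputation:
    """One pixel's LSTM reconstruction with input provenance per date."""

    estimate: np.ndarray  # (T,) index units, defined at every date
    provenance: np.ndarray  # (T,) int8 codes
    sigma_lstm: float  # forecast-error scale, NaN until assigned


def predict_hybrid(
    series: np.ndarray,
    model: LSTMNetwork,
    scaler: MinMaxScaler,
    config: LSTMConfig,
) -> PixelImputation:
    """Impute one gap series with the hybrid observed/recycled/fallback inputs.

    Walking forward in time, the input element for each date is the scaled
    observation if present, else the model's own earlier prediction for that
    date, else the linear-interpolation fallback. Dates inside the first
    window (which the next-step model cannot predict) carry the fallback
    value. Outputs are returned in index units.
    """
    series = np.asarray(series, dtype=float)
    T = series.size
    observed = np.isfinite(series)
    if not observed.any():
        raise ValueError("pixel has no valid dates; scaling cannot be anchored")
    W = config.window
    if T <= W:
        raise ValueError(f"series length {T} must exceed window {W}")

    scaled_obs = scaler.transform(series.reshape(-1, 1)).ravel()
    fallback = scaler.transform(linear_interpolate(series).reshape(-1, 1)).ravel()

    inputs = np.where(observed, scaled_obs, np.nan)
    provenance = np.where(observed, PROV_OBSERVED, PROV_FALLBACK).astype(np.int8)
    estimate_scaled = np.full(T, np.nan)

    for t in range(W, T):
        win = inputs[t - W : t]
        missing = ~np.isfinite(win)
        if missing.any():  # not yet predicted and not observed: fallback
            win = np.where(missing, fallback[t - W : t], win)
        estimate_scaled[t] = model.predict(win.reshape(1, W))[0]
        if not observed[t]:
            if np.isfinite(inputs[t]):
                pass  # already holds an earlier recycled prediction
            inputs[t] = estimate_scaled[t]
            provenance[t] = PROV_RECYCLED
    # Dates the model cannot reach (t < W): fallback estimates.
    estimate_scaled[:W] = fallback[:W]
    provenance[:W] = np.where(observed[:W], PROV_OBSERVED, PROV_FALLBACK)

    estimate = scaler.inverse_transform(estimate_scaled.reshape(-1, 1)).ravel()
    return PixelImputation(estimate=estimate, provenance=provenance, sigma_lstm=float("nan"))


def estimate_sigma_lstm(
    estimates: np.ndarray,
    observations: np.ndarray,
    min_residuals: int = 10,
    pool: np.ndarray | None = None,
) -> float:
    """Forecast-error scale: SD of (prediction - observation) at valid dates.

    With fewer than ``min_residuals`` paired dates the cluster-level residual
    ``pool`` is used instead; with no residuals anywhere an error is raised.
    Population standard deviation, in index units.
    """
    estimates = np.asarray(estimates, dtype=float)
    observations = np.asarray(observations, dtype=float)
    paired = np.isfinite(estimates) & np.isfinite(observations)
    resid = estimates[paired] - observations[paired]
    if resid.size >= min_residuals:
        return float(resid.std())
    if pool is not None and np.asarray(pool).size >= 1:
        return float(np.asarray(pool, dtype=float).std())
    if resid.size >= 1:
        return float(resid.std())
    raise ValueError("no residual pairs available to estimate sigma_lstm")


@dataclass
class LSTMCubeImputation:
    """Grid-wide LSTM imputation.

    ``sigma_lstm`` is +inf for pixels of small clusters that skipped
    training, which drives their fusion weight to zero downstream.
    """

    estimate: np.ndarray  # (T, ny, nx)
    sigma_lstm: np.ndarray  # (ny, nx)
    provenance: np.ndarray  # (T, ny, nx) int8
    histories: dict[int, TrainingHistory] = field(default_factory=dict)
    trained: dict[int, bool] = field(default_factory=dict)


def impute_lstm(
    cube: GapCube,
    assignment: ClusterAssignment,
    config: LSTMConfig | None = None,
) -> LSTMCubeImputation:
    """Train one model per (non-small) cluster and impute every member.

    The model is trained on the cluster reference (its most complete pixel,
    gaps bridged by the interpolation fallback); min-max scaling is fitted
    on the reference's training portion only and reused for all members.
    Small clusters skip training: their pixels carry the interpolation
    fallback as estimate and an infinite sigma so fusion falls back to the
    KF. Unassigned pixels (label -1) are treated the same way.
    """
    config = config or LSTMConfig()
    T, ny, nx = cube.shape
    est = np.full((T, ny, nx), np.nan)
    sig = np.full((ny, nx), np.inf)
    prov = np.full((T, ny, nx), PROV_FALLBACK, dtype=np.int8)
    histories: dict[int, TrainingHistory] = {}
    trained: dict[int, bool] = {}

    small = assignment.small
    for k in range(assignment.n_clusters):
        members = assignment.members(k)
        if small[k]:
            trained[k] = False
            for pid in members:
                _fallback_pixel(cube, pid, est, sig, prov)
            continue
        ref = assignment.references[k]
        ref_series = cube.series(ref)
        ref_filled = linear_interpolate(ref_series)
        n_pairs = T - config.window
        n_val = max(1, int(round(config.val_fraction * n_pairs)))
        train_end = config.window + (n_pairs - n_val)
        scaler = MinMaxScaler().fit(ref_filled[:train_end].reshape(-1, 1))
        try:
            model, hist = train_cluster_model(
                scaler.transform(ref_filled.reshape(-1, 1)).ravel(),
                LSTMConfig(**{**config.__dict__, "seed": config.seed + k}),
            )
        except ValueError:
            trained[k] = False
            for pid in members:
                _fallback_pixel(cube, pid, est, sig, prov)
            continue
        trained[k] = True
        histories[k] = hist

        cluster_resid: list[np.ndarray] = []
        pix_imps: dict[int, PixelImputation] = {}
        for pid in members:
            series = cube.series(pid)
            if not np.isfinite(series).any():
                continue
            imp = predict_hybrid(series, model, scaler, config)
            pix_imps[pid] = imp
            modelled = np.arange(T) >= config.window
            paired = modelled & np.isfinite(series)
            cluster_resid.append(imp.estimate[paired] - series[paired])
        pool = np.concatenate(cluster_resid) if cluster_resid else None
        for pid, imp in pix_imps.items():
            iy, ix = cube.pixel_index(pid)
            series = cube.values[:, iy, ix]
            modelled_est = np.where(np.arange(T) >= config.window, imp.estimate, np.nan)
            sig[iy, ix] = estimate_sigma_lstm(
                modelled_est, series, config.min_residuals, pool=pool
            )
            est[:, iy, ix] = imp.estimate
            prov[:, iy, ix] = imp.provenance

    # Pixels never touched (label -1, empty series): interpolation fallback.
    for pid in np.nonzero(assignment.labels < 0)[0]:
        _fallback_pixel(cube, pid, est, sig, prov)

    return LSTMCubeImputation(
        estimate=est, sigma_lstm=sig, provenance=prov, histories=histories, trained=trained
    )


def _fallback_pixel(cube, pid, est, sig, prov) -> None:
    iy, ix = cube.pixel_index(pid)
    series = cube.values[:, iy, ix]
    observed = np.isfinite(series)
    if observed.any():
        est[:, iy, ix] = linear_interpolate(series)
    else:
        est[:, iy, ix] = 0.0
    sig[iy, ix] = np.inf
    prov[:, iy, ix] = np.where(observed, PROV_OBSERVED, PROV_FALLBACK)
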