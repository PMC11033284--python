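"""Windowing, chronological splits, training loop and forecast metrics."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, clip_grad_norm
from .quatformer import (Quatformer, QuatformerConfig, omega_regularizer,
                         theta_regularizer, total_loss)
from .synthetic import ResidueSeries

__all__ = [
    "ForecastWindow",
    "MetricsReport",
    "Standardizer",
    "TrainingHistory",
    "make_windows",
    "split_windows",
    "train",
    "evaluate_metrics",
    "persistence_baseline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForecastWindow:
    """One supervised example: an input block and the step(s) right after it.

    ``inputs`` is (input_len, F) raw-scale — concentration (mg/kg) then
    covariates (temperature °C, humidity %).  ``target`` is the raw
    concentration over the forecast horizon.  ``anchor_day`` is the day index
    of the first input row.
    """

    series_id: str
    anchor_day: int
    inputs: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.inputs)) or np.any(~np.isfinite(self.target)):
            raise ValueError("windows must not contain missing values")


@dataclass(frozen=True)
class MetricsReport:
    """The five forecast-accuracy metrics (percentage ones on percent scale)."""

    mse: float
    rmse: float
    mae: float
    mape_pct: float
    smape_pct: float

    def as_dict(self) -> dict[str, float]:
        return {"mse": self.mse, "rmse": self.rmse, "mae": self.mae,
                "mape_pct": self.mape_pct, "smape_pct": self.smape_pct}


class Standardizer:
    """Column-wise z-scoring fit on training data only."""

    def __init__(self) -> None:
        self.mean: np.ndarray | None = None
        self.std: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "Standardizer":
        x = np.asarray(x, dtype=float)
        self.mean = x.mean(axis=0)
        std = x.std(axis=0)
        self.std = np.where(std > 0, std, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.std + self.mean


def series_key(s: ResidueSeries) -> str:
    return f"{s.pesticide}@{s.condition.temperature_C:g}C/{s.condition.rh_pct:g}%"


def make_windows(series_list, input_len: int = 7,
                 horizon: int = 1) -> list[ForecastWindow]:
    """Stride-1 sliding windows over every series.

    A series of length ``T`` yields ``T - input_len - horizon + 1`` windows;
    too-short series are skipped with a warning (error if all are skipped).
    """
    windows: list[ForecastWindow] = []
    skipped = 0
    for s in series_list:
        T = len(s)
        n_win = T - input_len - horizon + 1
        if n_win < 1:
            log.warning("series %s too short (%d) for input_len=%d horizon=%d",
                        series_key(s), T, input_len, horizon)
            skipped += 1
            continue
        cov = np.array([s.condition.temperature_C, s.condition.rh_pct])
        feats = np.column_stack([s.conc, np.tile(cov, (T, 1))])
        for a in range(n_win):
            windows.append(ForecastWindow(
                series_id=series_key(s),
                anchor_day=int(s.days[a]),
                inputs=feats[a:a + input_len],
                target=s.conc[a + input_len:a + input_len + horizon].copy(),
            ))
    if not windows:
        raise ValueError("every series was too short to window")
    return windows


def split_windows(windows, fractions=(0.7, 0.1, 0.2)):
    """Chronological train/val/test split within each series.

    Per series: first ``floor(n * f_train)`` anchors train, next
    ``floor(n * f_val)`` validate, remainder test — so no test anchor
    precedes a training anchor within any series (no future leakage).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    by_series: dict[str, list[ForecastWindow]] = {}
    for w in windows:
        by_series.setdefault(w.series_id, []).append(w)
    train, val, test = [], [], []
    for sid, ws in by_series.items():
        ws = sorted(ws, key=lambda w: w.anchor_day)
        n = len(ws)
        n_tr = int(np.floor(n * fractions[0]))
        n_va = int(np.floor(n * fractions[1]))
        train += ws[:n_tr]
        val += ws[n_tr:n_tr + n_va]
        test += ws[n_tr + n_va:]
    if not train or not val or not test:
        raise ValueError("split produced an empty partition; adjust fractions")
    return train, val, test


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_pred_loss: list[float] = field(default_factory=list)
    omega_loss: list[float] = field(default_factory=list)
    theta_loss: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)
    val_pred_loss: list[float] = field(default_factory=list)


def _window_arrays(windows, model: Quatformer):
    x = np.stack([w.inputs for w in windows])
    y = np.stack([w.target for w in windows])
    xs = model.standardize(x)
    ys = (y - model.conc_mean) / model.conc_std
    return xs, ys


def train(config: QuatformerConfig, train_windows, val_windows,
          model: Quatformer | None = None):
    """Fit a Quatformer on raw-scale windows by mini-batch Adam.

    Standardization statistics come from the training windows only.  Early
    stopping watches the validation prediction loss with the configured
    patience, restoring the best parameters.  Returns ``(model, history)``.
    """
    if not train_windows or not val_windows:
        raise ValueError("train and validation partitions must be non-empty")
    model = model or Quatformer(config)
    tr_in = np.stack([w.inputs for w in train_windows])
    tr_tg = np.stack([w.target for w in train_windows])
    conc = np.concatenate([tr_in[:, :, 0].ravel(), tr_tg.ravel()])
    cov = tr_in[:, :, 1:].reshape(-1, config.n_features - 1)
    conc_std = conc.std() or 1.0
    cov_std = np.where(cov.std(axis=0) > 0, cov.std(axis=0), 1.0)
    model.set_scaler(conc.mean(), conc_std, cov.mean(axis=0), cov_std)

    x_tr, y_tr = _window_arrays(train_windows, model)
    x_va, y_va = _window_arrays(val_windows, model)

    params = model.params()
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = TrainingHistory()
    best_val = np.inf
    best_state = [p.data.copy() for p in params]
    bad_epochs = 0
    n = len(train_windows)
    for epoch in range(config.epochs):
        # cosine decay to 1% of the base rate over the epoch budget
        opt.lr = config.learning_rate * (
            0.01 + 0.99 * 0.5 * (1 + np.cos(np.pi * epoch / max(config.epochs - 1, 1))))
        order = rng.permutation(n)
        ep_pred, ep_om, ep_th, ep_tot, n_batches = 0.0, 0.0, 0.0, 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            collect: list = []
            pred = model.forward(x_tr[idx], collect)
            oms = [c[0] for c in collect]
            ths = [c[1] for c in collect]
            l_pred = total_loss(pred, Tensor(y_tr[idx]))
            loss = total_loss(pred, Tensor(y_tr[idx]), oms, ths,
                              config.lambda1, config.lambda2)
            if not np.isfinite(float(loss.data)):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            clip_grad_norm(params, config.grad_clip)
            opt.step()
            ep_pred += float(l_pred.data)
            ep_tot += float(loss.data)
            # the two regularizer components, re-evaluated for the history
            l_om = float(np.mean([float(Tensor._lift(omega_regularizer(o)).data)
                                  for o in oms])) if oms else 0.0
            l_th = float(np.mean([float(Tensor._lift(theta_regularizer(t)).data)
                                  for t in ths])) if ths else 0.0
            ep_om += l_om
            ep_th += l_th
            n_batches += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val_pred = model.forward(x_va).data
        val_loss = float(np.mean((val_pred - y_va) ** 2))
        history.epochs.append(epoch)
        history.train_pred_loss.append(ep_pred / n_batches)
        history.omega_loss.append(ep_om / n_batches)
        history.theta_loss.append(ep_th / n_batches)
        history.total.append(ep_tot / n_batches)
        history.val_pred_loss.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = [p.data.copy() for p in params]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    for p, s in zip(params, best_state):
        p.data = s
    model.trained = True
    return model, history


def predict_windows(model: Quatformer, windows) -> np.ndarray:
    """Raw-scale (mg/kg) predictions for a list of windows, shape (n, horizon)."""
    x = np.stack([w.inputs for w in windows])
    xs = model.standardize(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = model.forward(xs).data
    return pred * model.conc_std + model.conc_mean


def evaluate_metrics(y_true, y_pred) -> MetricsReport:
    """The five accuracy metrics: MSE, RMSE, MAE and percent MAPE / SMAPE.

    MAPE terms with a zero truth and nonzero prediction are infinite (a
    warning is issued, not an exception); exact 0/0 terms contribute zero,
    for MAPE and SMAPE alike.
    """
    y = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if y.size == 0 or y.size != p.size:
        raise ValueError("y_true and y_pred must be equal nonzero length")
    err = p - y
    mse = float(np.mean(err ** 2))
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(err)))
    abs_err = np.abs(err)
    with np.errstate(divide="ignore", invalid="ignore"):
        ape = np.where(abs_err == 0, 0.0, abs_err / np.abs(y))
        denom = (np.abs(p) + np.abs(y)) / 2.0
        sape = np.where(abs_err == 0, 0.0, abs_err / denom)
    if np.any(np.isinf(ape)):
        warnings.warn("MAPE is infinite: zero truth with nonzero prediction",
                      stacklevel=2)
    mape = float(100.0 * np.mean(ape))
    smape = float(100.0 * np.mean(sape))
    return MetricsReport(mse=mse, rmse=rmse, mae=mae,
                         mape_pct=mape, smape_pct=smape)


def persistence_baseline(window: ForecastWindow, horizon: int | None = None) -> np.ndarray:
    """Naive forecast: repeat the last observed concentration."""
    h = horizon if horizon is not None else len(window.target)
    return np.full(h, window.inputs[-1, 0])
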