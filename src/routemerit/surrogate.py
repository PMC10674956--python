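"""Sequence-to-one LSTM regressor predicting route output merit.

The network is the standard four-layer recurrent regression stack: a sequence
input, one LSTM layer (default 100 hidden units), a fully connected layer and
a scalar regression output trained with Adam on mean squared error.  The
55-value merit vector of a route is presented, by default, as a single time
step with 55 channels; a ``sequence_mode="steps"`` flag offers the alternative
length-55 / one-channel reading.

Implemented directly on numpy: forward pass, backpropagation through time and
Adam updates live here, which keeps training end-to-end reproducible from a
single integer seed (gradients are verified against finite differences in the
test suite).  Training keeps the parameter state with the best validation
loss, mirroring common deep-learning practice for small, noisy tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .routes import RouteMatrix


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SurrogateConfig:
    """Training options for the LSTM surrogate.

    ``epochs=2000`` with early stopping (patience 200) is the desk-scale
    default; :meth:`paper_preset` restores the long-run schedule (100000
    epochs, no early stopping).  Inputs and targets are scaled from the 0-100
    merit range into [0, 1] unless ``scale`` is disabled.
    """

    input_size: int = 55
    hidden_units: int = 100
    epochs: int = 2000
    learning_rate: float = 0.0005
    seed: int = 0
    val_fraction: float = 0.2
    patience: int | None = 200
    sequence_mode: str = "channels"  # or "steps"
    scale: bool = True

    def __post_init__(self) -> None:
        if self.input_size <= 0 or self.hidden_units <= 0 or self.epochs <= 0:
            raise ConfigurationError("sizes and epochs must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.sequence_mode not in ("channels", "steps"):
            raise ConfigurationError(f"unknown sequence_mode {self.sequence_mode!r}")

    @classmethod
    def paper_preset(cls, seed: int = 0, **kw) -> "SurrogateConfig":
        return cls(epochs=100000, patience=None, seed=seed, **kw)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _init_params(cfg: SurrogateConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    D = 1 if cfg.sequence_mode == "steps" else cfg.input_size
    H = cfg.hidden_units

    def glorot(rows, cols):
        s = np.sqrt(6.0 / (rows + cols))
        return rng.uniform(-s, s, size=(rows, cols))

    b = np.zeros(4 * H)
    b[H:2 * H] = 1.0  # forget-gate bias
    return {
        "Wx": glorot(4 * H, D),
        "Wh": glorot(4 * H, H),
        "b": b,
        "wy": glorot(1, H)[0],
        "by": np.zeros(1),
    }


def _as_sequences(X: np.ndarray, cfg: SurrogateConfig) -> np.ndarray:
    """(N, features) -> (N, T, D) per the configured sequence reading."""
    if X.shape[1] != cfg.input_size:
        raise ConfigurationError(
            f"expected {cfg.input_size} input channels, got {X.shape[1]}"
        )
    if cfg.sequence_mode == "steps":
        return X[:, :, None]  # T = input_size, D = 1
    return X[:, None, :]  # T = 1, D = input_size


def _forward(params: Mapping[str, np.ndarray], seq: np.ndarray, cache: bool = False):
    N, T, D = seq.shape
    H = params["wy"].shape[0]
    h = np.zeros((N, H))
    c = np.zeros((N, H))
    caches = []
    for t in range(T):
        x = seq[:, t, :]
        z = x @ params["Wx"].T + h @ params["Wh"].T + params["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev = h
        h = o * tc
        if cache:
            caches.append((x, h_prev, c_prev, i, f, g, o, tc))
    y = h @ params["wy"] + params["by"][0]
    return (y, h, caches) if cache else y


def _loss_and_grads(params, seq, targets):
    N, T, D = seq.shape
    H = params["wy"].shape[0]
    y, hT, caches = _forward(params, seq, cache=True)
    err = y - targets
    loss = float(np.mean(err ** 2))
    dy = 2.0 * err / N

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["wy"] = hT.T @ dy
    grads["by"][0] = dy.sum()
    dh = dy[:, None] * params["wy"][None, :]
    dc = np.zeros((N, H))
    for t in range(T - 1, -1, -1):
        x, h_prev, c_prev, i, f, g, o, tc = caches[t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc ** 2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ],
            axis=1,
        )
        grads["Wx"] += dz.T @ x
        grads["Wh"] += dz.T @ h_prev
        grads["b"] += dz.sum(axis=0)
        dh = dz @ params["Wh"]
        dc = dc * f
    return loss, grads


@dataclass
class TrainedSurrogate:
    """Fitted surrogate: opaque parameters plus config echo and history."""

    params: dict
    config: SurrogateConfig
    history: pd.DataFrame
    best_val_loss: float
    best_epoch: int

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if self.config.scale:
            arr = arr / 100.0
        y = _forward(self.params, _as_sequences(arr, self.config))
        return y * 100.0 if self.config.scale else y

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            __config__=json.dumps(asdict(self.config)),
            __best__=np.array([self.best_val_loss, self.best_epoch]),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedSurrogate":
        with np.load(path, allow_pickle=False) as z:
            cfg = SurrogateConfig(**json.loads(str(z["__config__"])))
            best = z["__best__"]
            params = {
                k: z[k] for k in ("Wx", "Wh", "b", "wy", "by")
            }
        return cls(params, cfg, pd.DataFrame(), float(best[0]), int(best[1]))


def train_surrogate(
    matrix: RouteMatrix,
    config: SurrogateConfig,
    split: Mapping[str, Sequence[int]] | None = None,
) -> TrainedSurrogate:
    """Train the LSTM on the route matrix under a train/validation(/test) split.

    ``split`` maps ``"train"``/``"validation"`` (and optionally ``"test"``) to
    disjoint route positions.  When omitted, a seeded validation carve-out of
    ``config.val_fraction`` is drawn from all routes.  Checkpointing keeps the
    parameters with the lowest validation loss.
    """
    X = matrix.cells.to_numpy(dtype=float)
    y = matrix.output_merit.to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)
    n = len(y)
    if split is None:
        order = rng.permutation(n)
        n_val = max(1, int(round(config.val_fraction * n)))
        split = {"validation": order[:n_val], "train": order[n_val:]}
    tr = np.asarray(split["train"], dtype=int)
    va = np.asarray(split.get("validation", []), dtype=int)
    groups = [np.asarray(split[k], dtype=int) for k in split]
    flat = np.concatenate(groups) if groups else np.array([], dtype=int)
    if len(np.unique(flat)) != len(flat):
        raise ConfigurationError("split index sets must be disjoint")
    if tr.size == 0:
        raise ConfigurationError("training set is empty")
    if va.size == 0:
        raise ConfigurationError(
            "validation set is empty but checkpointing is best-validation"
        )

    scalef = 100.0 if config.scale else 1.0
    seq_tr = _as_sequences(X[tr] / scalef, config)
    y_tr = y[tr] / scalef
    seq_va = _as_sequences(X[va] / scalef, config)
    y_va = y[va] / scalef

    params = _init_params(config, rng)
    mom = {k: np.zeros_like(v) for k, v in params.items()}
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best = {k: v.copy() for k, v in params.items()}
    best_val = np.inf
    best_epoch = 0
    bad_epochs = 0
    hist = {"epoch": [], "train_loss": [], "val_loss": []}
    for epoch in range(1, config.epochs + 1):
        loss, grads = _loss_and_grads(params, seq_tr, y_tr)
        for k in params:
            mom[k] = beta1 * mom[k] + (1 - beta1) * grads[k]
            vel[k] = beta2 * vel[k] + (1 - beta2) * grads[k] ** 2
            mhat = mom[k] / (1 - beta1 ** epoch)
            vhat = vel[k] / (1 - beta2 ** epoch)
            params[k] = params[k] - config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        val_pred = _forward(params, seq_va)
        val_loss = float(np.mean((val_pred - y_va) ** 2))
        hist["epoch"].append(epoch)
        hist["train_loss"].append(loss)
        hist["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best = {k: v.copy() for k, v in params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if config.patience is not None and bad_epochs >= config.patience:
                break
    return TrainedSurrogate(
        best, config, pd.DataFrame(hist), best_val, best_epoch
    )


class SurrogateModel:
    """Estimator-style front end: ``SurrogateModel(matrix, config).fit()``."""

    def __init__(self, matrix: RouteMatrix, config: SurrogateConfig | None = None):
        self.matrix = matrix
        self.config = config or SurrogateConfig(input_size=matrix.n_metabolites)

    def fit(self, split: Mapping[str, Sequence[int]] | None = None) -> TrainedSurrogate:
        return train_surrogate(self.matrix, self.config, split)


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SSres / SStot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = float(((y_true - y_pred) ** 2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


@dataclass
class EvalReport:
    """Repeated-holdout evaluation summary."""

    per_repeat_r2: list[float]
    n_test: int
    n_repeats: int
    seeds: list[int]

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.per_repeat_r2))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "per_repeat_r2": self.per_repeat_r2,
                    "mean_r2": self.mean_r2,
                    "n_test": self.n_test,
                    "n_repeats": self.n_repeats,
                    "seeds": self.seeds,
                },
                indent=2,
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"seed": self.seeds, "r2": self.per_repeat_r2})


def repeated_holdout_r2(
    matrix: RouteMatrix,
    config: SurrogateConfig,
    n_test: int = 5,
    n_repeats: int = 10,
    seeds: Sequence[int] | None = None,
) -> EvalReport:
    """Repeatedly hold out ``n_test`` routes, train on the rest, collect R².

    Each repeat draws its test quintet without replacement (re-sampled across
    repeats), carves a validation set out of the remaining routes, trains
    from scratch and scores the held-out predictions.
    """
    if n_repeats < 1:
        raise ConfigurationError("n_repeats must be >= 1")
    n = matrix.n_routes
    if not (0 < n_test < n):
        raise ConfigurationError(f"n_test={n_test} must be in 1..{n - 1}")
    if seeds is None:
        seeds = [config.seed + 1000 * r for r in range(n_repeats)]
    if len(seeds) != n_repeats:
        raise ConfigurationError("need one seed per repeat")
    r2s = []
    X = matrix.cells.to_numpy(dtype=float)
    y = matrix.output_merit.to_numpy(dtype=float)
    for seed in seeds:
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        test = order[:n_test]
        rest = order[n_test:]
        n_val = max(1, int(round(config.val_fraction * len(rest))))
        split = {"test": test, "validation": rest[:n_val], "train": rest[n_val:]}
        cfg = SurrogateConfig(**{**asdict(config), "seed": int(seed)})
        model = train_surrogate(matrix, cfg, split)
        pred = model.predict(X[test])
        r2s.append(r_squared(y[test], pred))
    return EvalReport(r2s, n_test, n_repeats, [int(s) for s in seeds])
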