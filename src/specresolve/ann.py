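"""Feed-forward purelin network trained by Levenberg–Marquardt.

The architecture mirrors toolbox-era spectroscopic practice: one input node
per wavelength in the working window (81 by default), a hidden layer (default
five neurons) and four linear outputs, with linear ("purelin") transfer on
both layers — so the trained network composes to a single affine map, and its
value over a direct least-squares fit is the regularization implicit in damped
small-step training with early stopping. Inputs and targets are scaled to
[−1, 1] per feature (mapminmax style). Training minimizes the sum of squared
residuals over the training split with Levenberg–Marquardt steps on the full
weight vector: the damping μ is divided by ``mu_dec`` after an accepted step
and multiplied by ``mu_inc`` after a rejected one, so the training MSE is
non-increasing across accepted steps. The calibration samples are split
(default 70/15/15) into training/validation/test subsets by a seeded shuffle;
training stops early when the validation MSE has risen for six consecutive
epochs, and the returned weights are those of the best validation epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthetic_data import SpectraSet

__all__ = ["ANNConfig", "ANNModel", "MinMaxScaler", "train_ann", "predict_ann",
           "affine_map", "training_diagnostics"]


@dataclass(frozen=True)
class ANNConfig:
    """Architecture and training schedule of the purelin network."""

    n_hidden: int = 5
    max_epochs: int = 100
    mu_init: float = 0.1
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    patience: int = 6
    goal_mse: float = 1e-16          # scaled-space training target

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class MinMaxScaler:
    """mapminmax-style scaling of each feature to [−1, 1]."""

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        return cls(X.min(axis=0), X.max(axis=0))

    def _span(self) -> np.ndarray:
        span = self.maxs - self.mins
        return np.where(span == 0, 1.0, span)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.mins) / self._span() - 1.0

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        return (Xs + 1.0) / 2.0 * self._span() + self.mins


@dataclass
class ANNModel:
    """Trained network weights, scalers and the per-epoch MSE history."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    x_scaler: MinMaxScaler
    y_scaler: MinMaxScaler
    history: dict
    best_epoch: int
    split_indices: dict
    config: ANNConfig
    wavelengths_nm: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "x_scaler": {"mins": self.x_scaler.mins.tolist(),
                         "maxs": self.x_scaler.maxs.tolist()},
            "y_scaler": {"mins": self.y_scaler.mins.tolist(),
                         "maxs": self.y_scaler.maxs.tolist()},
            "history": {k: list(map(float, v)) for k, v in self.history.items()},
            "best_epoch": self.best_epoch,
            "split_indices": {k: list(map(int, v)) for k, v in self.split_indices.items()},
            "config": {
                "n_hidden": self.config.n_hidden,
                "max_epochs": self.config.max_epochs,
                "mu_init": self.config.mu_init,
                "mu_inc": self.config.mu_inc,
                "mu_dec": self.config.mu_dec,
                "mu_max": self.config.mu_max,
                "split_fractions": list(self.config.split_fractions),
                "seed": self.config.seed,
                "patience": self.config.patience,
            },
            "wavelengths_nm": None if self.wavelengths_nm is None
            else self.wavelengths_nm.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "ANNModel":
        d = json.loads(Path(path).read_text())
        cfg = dict(d["config"])
        cfg["split_fractions"] = tuple(cfg["split_fractions"])
        return cls(
            W1=np.asarray(d["W1"], dtype=float), b1=np.asarray(d["b1"], dtype=float),
            W2=np.asarray(d["W2"], dtype=float), b2=np.asarray(d["b2"], dtype=float),
            x_scaler=MinMaxScaler(np.asarray(d["x_scaler"]["mins"]),
                                  np.asarray(d["x_scaler"]["maxs"])),
            y_scaler=MinMaxScaler(np.asarray(d["y_scaler"]["mins"]),
                                  np.asarray(d["y_scaler"]["maxs"])),
            history=d["history"],
            best_epoch=int(d["best_epoch"]),
            split_indices={k: np.asarray(v, dtype=int) for k, v in d["split_indices"].items()},
            config=ANNConfig(**cfg),
            wavelengths_nm=None if d["wavelengths_nm"] is None
            else np.asarray(d["wavelengths_nm"], dtype=float),
        )


def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(p, n_in, n_hidden, n_out):
    i = 0
    W1 = p[i:i + n_hidden * n_in].reshape(n_hidden, n_in); i += n_hidden * n_in
    b1 = p[i:i + n_hidden]; i += n_hidden
    W2 = p[i:i + n_out * n_hidden].reshape(n_out, n_hidden); i += n_out * n_hidden
    b2 = p[i:i + n_out]
    return W1, b1, W2, b2


def _forward(W1, b1, W2, b2, X):
    return (X @ W1.T + b1) @ W2.T + b2


def _jacobian(W1, b1, W2, b2, X):
    """Jacobian of the flattened residual vector w.r.t. the packed weights.

    Residuals are ordered sample-major then output; with linear transfers the
    per-sample Jacobian blocks are exact (no approximation).
    """
    n, n_in = X.shape
    n_hidden, n_out = W1.shape[0], W2.shape[0]
    H = X @ W1.T + b1                                     # n × hidden
    P = n_hidden * n_in + n_hidden + n_out * n_hidden + n_out
    J = np.zeros((n * n_out, P))
    # dW1[j,i]: dy_o/dW1[j,i] = W2[o,j] * x_i
    blk = (W2[None, :, :, None] * X[:, None, None, :])    # n × out × hidden × in
    J[:, : n_hidden * n_in] = blk.reshape(n * n_out, n_hidden * n_in)
    # b1[j]: W2[o,j]
    J[:, n_hidden * n_in: n_hidden * n_in + n_hidden] = np.tile(W2, (n, 1))
    # W2[o,j]: h_j on the o-th output rows only
    off = n_hidden * n_in + n_hidden
    w2blk = np.zeros((n, n_out, n_out, n_hidden))
    idx = np.arange(n_out)
    w2blk[:, idx, idx, :] = H[:, None, :]
    J[:, off: off + n_out * n_hidden] = w2blk.reshape(n * n_out, n_out * n_hidden)
    # b2[o]
    off += n_out * n_hidden
    J[:, off:] = np.tile(np.eye(n_out), (n, 1))
    return J


def _split(n: int, fractions, rng) -> dict:
    idx = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = max(1, min(n_train, n))
    return {
        "train": np.sort(idx[:n_train]),
        "val": np.sort(idx[n_train:n_train + n_val]),
        "test": np.sort(idx[n_train + n_val:]),
    }


def train_ann(X, Y, config: ANNConfig | None = None) -> ANNModel:
    """Train the purelin network on windowed spectra and concentrations."""
    config = config or ANNConfig()
    wavelengths = None
    if isinstance(X, SpectraSet):
        wavelengths = X.wavelengths_nm
        X = X.absorbance
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, n_in = X.shape
    n_out = Y.shape[1]
    rng = np.random.default_rng(config.seed)
    splits = _split(n, config.split_fractions, rng)
    if splits["train"].size < 1:
        raise ValueError("training split is empty")

    x_scaler = MinMaxScaler.fit(X)
    y_scaler = MinMaxScaler.fit(Y)
    Xs, Ys = x_scaler.transform(X), y_scaler.transform(Y)
    Xtr, Ytr = Xs[splits["train"]], Ys[splits["train"]]

    # small fan-in-scaled uniform init
    W1 = rng.uniform(-0.5, 0.5, (config.n_hidden, n_in)) / np.sqrt(n_in)
    b1 = rng.uniform(-0.5, 0.5, config.n_hidden)
    W2 = rng.uniform(-0.5, 0.5, (n_out, config.n_hidden)) / np.sqrt(config.n_hidden)
    b2 = rng.uniform(-0.5, 0.5, n_out)

    def mse_of(params, rows):
        if rows.size == 0:
            return np.nan
        w1, c1, w2, c2 = _unpack(params, n_in, config.n_hidden, n_out)
        r = _forward(w1, c1, w2, c2, Xs[rows]) - Ys[rows]
        return float(np.mean(r * r))

    p = _pack(W1, b1, W2, b2)
    mu = config.mu_init
    history = {"train": [], "val": [], "test": []}
    best_val = np.inf
    best_p = p.copy()
    best_epoch = 0
    n_rising = 0
    have_val = splits["val"].size > 0

    for epoch in range(1, config.max_epochs + 1):
        w1, c1, w2, c2 = _unpack(p, n_in, config.n_hidden, n_out)
        R = _forward(w1, c1, w2, c2, Xtr) - Ytr
        sse = float(np.sum(R * R))
        J = _jacobian(w1, c1, w2, c2, Xtr)
        g = J.T @ R.ravel()
        JtJ = J.T @ J
        accepted = False
        solvable = False
        while mu <= config.mu_max:
            try:
                step = np.linalg.solve(JtJ + mu * np.eye(JtJ.shape[0]), g)
            except np.linalg.LinAlgError:
                mu *= config.mu_inc
                continue
            solvable = True
            p_new = p - step
            w1n, c1n, w2n, c2n = _unpack(p_new, n_in, config.n_hidden, n_out)
            Rn = _forward(w1n, c1n, w2n, c2n, Xtr) - Ytr
            if float(np.sum(Rn * Rn)) < sse:
                accepted = True
                p = p_new
                mu = max(mu * config.mu_dec, 1e-20)
                break
            mu *= config.mu_inc
        if not accepted:
            if not solvable:
                raise RuntimeError(
                    "Levenberg–Marquardt normal equations stayed singular up to the damping ceiling"
                )
            # no damped step improves the fit: the optimum is reached
            history["train"].append(mse_of(p, splits["train"]))
            history["val"].append(mse_of(p, splits["val"]))
            history["test"].append(mse_of(p, splits["test"]))
            monitor = history["val"][-1] if have_val else history["train"][-1]
            if monitor < best_val - 1e-18:
                best_val, best_p, best_epoch = monitor, p.copy(), epoch
            break

        history["train"].append(mse_of(p, splits["train"]))
        history["val"].append(mse_of(p, splits["val"]))
        history["test"].append(mse_of(p, splits["test"]))

        monitor = history["val"][-1] if have_val else history["train"][-1]
        if monitor < best_val - 1e-18:
            best_val = monitor
            best_p = p.copy()
            best_epoch = epoch
            n_rising = 0
        else:
            n_rising += 1
            if have_val and n_rising >= config.patience:
                break
        if history["train"][-1] <= config.goal_mse:
            if not have_val or history["val"][-1] <= best_val:
                best_p, best_epoch = p.copy(), epoch
            break

    W1, b1, W2, b2 = _unpack(best_p, n_in, config.n_hidden, n_out)
    return ANNModel(
        W1=W1, b1=b1, W2=W2, b2=b2,
        x_scaler=x_scaler, y_scaler=y_scaler,
        history=history, best_epoch=best_epoch,
        split_indices=splits, config=config,
        wavelengths_nm=wavelengths,
    )


def predict_ann(model: ANNModel, X_new) -> np.ndarray:
    """Predicted concentrations for new spectra (scale → affine → unscale)."""
    if isinstance(X_new, SpectraSet):
        X_new = X_new.absorbance
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.W1.shape[1]:
        raise ValueError("column count of X_new does not match the trained network")
    Ys = _forward(model.W1, model.b1, model.W2, model.b2,
                  model.x_scaler.transform(X_new))
    return model.y_scaler.inverse(Ys)


def affine_map(model: ANNModel) -> tuple[np.ndarray, np.ndarray]:
    """Collapse the network (with its scalers) to ``y = A x + c`` in raw units."""
    # scaled: ys = W2 W1 xs + (W2 b1 + b2)
    A_s = model.W2 @ model.W1
    c_s = model.W2 @ model.b1 + model.b2
    sx = model.x_scaler._span()
    sy = model.y_scaler._span()
    # xs = 2(x - xmin)/sx - 1 ; y = (ys + 1)/2 * sy + ymin
    A = (sy[:, None] / 2.0) * A_s * (2.0 / sx)[None, :]
    c = (sy / 2.0) * (c_s - A_s @ (2.0 * model.x_scaler.mins / sx + 1.0) + 1.0) \
        + model.y_scaler.mins
    return A, c


def training_diagnostics(model: ANNModel, X, Y) -> dict:
    """Per-split predicted-vs-target regression (slope, intercept, r, MSE).

    Pools all output channels within a split, matching the usual toolbox
    regression diagram; also returns the MSE history and best epoch.
    """
    if isinstance(X, SpectraSet):
        X = X.absorbance
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    pred = predict_ann(model, X)
    report = {"best_epoch": model.best_epoch, "history": model.history, "splits": {}}
    for name, rows in model.split_indices.items():
        if rows.size == 0:
            continue
        t = Y[rows].ravel()
        y = pred[rows].ravel()
        if np.ptp(t) == 0:
            slope, intercept, r = np.nan, float(np.mean(y)), np.nan
        else:
            slope, intercept = np.polyfit(t, y, 1)
            r = float(np.corrcoef(t, y)[0, 1])
        report["splits"][name] = {
            "slope": float(slope),
            "intercept": float(intercept),
            "r": r,
            "mse": float(np.mean((y - t) ** 2)),
            "n": int(rows.size),
        }
    return report
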