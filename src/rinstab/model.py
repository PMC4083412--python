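"""Single-hidden-layer neural regressor for stability change (ddG) prediction.

The network has one tanh hidden layer (5 units by default) and a linear
output, trained by per-sample gradient descent with momentum on squared
error.  Training holds out 15% of the rows as a validation set and stops
once validation RMSE has not improved for `patience` consecutive epochs,
returning the parameters of the best-validation epoch.  Inputs and target
are standardized by training-split statistics; predictions are returned on
the original kcal/mol scale.

Sign convention: positive ddG = destabilizing (configurable downstream).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._aa import ONE_TO_THREE, is_standard

__all__ = [
    "MutationRecord",
    "TrainedModel",
    "train",
    "predict",
    "cross_validate",
    "save_model",
    "load_model",
]


def _norm_aa(aa: str) -> str:
    aa = aa.strip().upper()
    if len(aa) == 1:
        aa = ONE_TO_THREE.get(aa, aa)
    if not is_standard(aa):
        raise ValueError(f"non-standard residue code: {aa!r}")
    return aa


@dataclass
class MutationRecord:
    """One single-site substitution with its environment.

    `position` is the author residue number (plus insertion code) as a
    string; `ddg_exp` is the experimental stability change in kcal/mol
    when known.
    """

    pdb_id: str
    chain: str
    position: str
    wt_aa: str
    mut_aa: str
    ph: float = 7.0
    temperature: float = 25.0
    ddg_exp: float | None = None

    def __post_init__(self) -> None:
        self.wt_aa = _norm_aa(self.wt_aa)
        self.mut_aa = _norm_aa(self.mut_aa)
        self.position = str(self.position).strip()
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"wild-type and mutant residue are identical: {self.wt_aa}")
        if not math.isfinite(self.temperature):
            raise ValueError("temperature must be finite")

    @property
    def key(self) -> tuple:
        return (self.pdb_id, self.chain, self.position, self.wt_aa, self.mut_aa,
                self.ph, self.temperature)


@dataclass
class TrainedModel:
    input_dim: int
    hidden_units: int
    w1: np.ndarray  # (hidden, input)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    activation: str = "tanh"
    history: dict = field(default_factory=dict)
    best_epoch: int = -1
    seed: int = 0
    manifest_hash: str | None = None
    sign_convention: str = "positive_destabilizing"


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(z) if kind == "tanh" else z


def _act_grad(h: np.ndarray, kind: str) -> np.ndarray:
    return 1.0 - h * h if kind == "tanh" else np.ones_like(h)


def _forward_std(w1, b1, w2, b2, xs: np.ndarray, activation: str) -> np.ndarray:
    h = _act(xs @ w1.T + b1, activation)
    return h @ w2 + b2


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def train(
    X: np.ndarray,
    y: np.ndarray,
    hidden_units: int = 5,
    val_fraction: float = 0.15,
    patience: int = 5,
    seed: int = 0,
    max_epochs: int = 500,
    learning_rate: float = 0.01,
    momentum: float = 0.9,
    activation: str = "tanh",
    batch_size: int = 32,
    manifest_hash: str | None = None,
    improvement_tol: float = 1e-6,
) -> TrainedModel:
    """Fit the regressor with validation-split early stopping.

    Weights start from a seeded uniform(-0.5, 0.5).  Returns the parameters
    from the epoch with the lowest validation RMSE.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y length")
    n, d = X.shape
    if n < 10:
        raise ValueError(f"too few rows to train: {n} < 10")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite (no missing values)")
    if float(np.std(y)) == 0.0:
        warnings.warn("target has zero variance; model will train to a constant")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if val_fraction > 0 else 0
    val_idx = order[n - n_val:] if n_val else np.array([], dtype=int)
    tr_idx = order[: n - n_val] if n_val else order

    # Range scaling to [-1, 1] by training-split min/max (the convention of
    # classic MLP trainers; keeps per-sample lr 0.3 updates stable).
    x_min = X[tr_idx].min(axis=0)
    x_max = X[tr_idx].max(axis=0)
    x_mean = (x_min + x_max) / 2.0
    x_scale = (x_max - x_min) / 2.0
    x_scale[x_scale < 1e-12] = 1.0
    y_min, y_max = float(y[tr_idx].min()), float(y[tr_idx].max())
    y_mean = (y_min + y_max) / 2.0
    y_scale = (y_max - y_min) / 2.0
    if y_scale < 1e-12:
        y_scale = 1.0
    xs_tr = (X[tr_idx] - x_mean) / x_scale
    ys_tr = (y[tr_idx] - y_mean) / y_scale
    xs_val = (X[val_idx] - x_mean) / x_scale if n_val else xs_tr
    ys_val = (y[val_idx] - y_mean) / y_scale if n_val else ys_tr

    # flat parameter vector: [w1, b1, w2, b2]; input-layer weights are
    # fan-in scaled so hidden tanh units start in their linear regime, and
    # the output layer starts at zero (the scaled-target mean)
    n_par = hidden_units * d + hidden_units + hidden_units + 1
    theta = rng.uniform(-0.5, 0.5, size=n_par)
    theta[: hidden_units * d] /= np.sqrt(d)
    theta[hidden_units * (d + 1):] = 0.0

    def unpack(t: np.ndarray):
        ofs = hidden_units * d
        return (t[:ofs].reshape(hidden_units, d), t[ofs:ofs + hidden_units],
                t[ofs + hidden_units:ofs + 2 * hidden_units], float(t[-1]))

    def batch_grad(t: np.ndarray, xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = unpack(t)
        h = _act(xb @ w1.T + b1, activation)
        g_out = ((h @ w2 + b2) - yb) / len(yb)
        g_h = (g_out[:, None] * w2[None, :]) * _act_grad(h, activation)
        return np.concatenate([
            (g_h.T @ xb).ravel(), g_h.sum(axis=0), h.T @ g_out, [g_out.sum()],
        ])

    best = {"val": np.inf, "epoch": -1, "theta": theta.copy()}
    history: dict[str, list[float]] = {"train_rmse": [], "val_rmse": []}
    stall = 0
    n_tr = xs_tr.shape[0]
    # Polyak-style averaged iterate: epochs are scored (and the returned
    # parameters taken) from this average, which damps mini-batch noise so
    # the patience rule measures a true validation plateau
    theta_avg = theta.copy()
    avg_decay = 0.9
    # Adam-style moments: `momentum` is the first-moment decay
    m1 = np.zeros(n_par)
    m2 = np.zeros(n_par)
    m2_max = np.zeros(n_par)
    beta2 = 0.999
    step = 0
    for epoch in range(max_epochs):
        # one epoch = a shuffled pass of adaptive mini-batch gradient steps
        order_ep = rng.permutation(n_tr)
        for start in range(0, n_tr, batch_size):
            idx = order_ep[start:start + batch_size]
            g = batch_grad(theta, xs_tr[idx], ys_tr[idx])
            step += 1
            m1 = momentum * m1 + (1 - momentum) * g
            m2 = beta2 * m2 + (1 - beta2) * g * g
            m2_max = np.maximum(m2_max, m2)  # AMSGrad: non-increasing step
            m1_hat = m1 / (1 - momentum**step)
            m2_hat = m2_max / (1 - beta2**step)
            theta = theta - learning_rate * m1_hat / (np.sqrt(m2_hat) + 1e-8)
            theta_avg = avg_decay * theta_avg + (1 - avg_decay) * theta
        w1, b1, w2, b2 = unpack(theta_avg)
        tr_rmse = _rmse(_forward_std(w1, b1, w2, b2, xs_tr, activation), ys_tr)
        val_rmse = _rmse(_forward_std(w1, b1, w2, b2, xs_val, activation), ys_val)
        history["train_rmse"].append(tr_rmse * y_scale)
        history["val_rmse"].append(val_rmse * y_scale)
        if val_rmse < best["val"] - improvement_tol:
            best = {"val": val_rmse, "epoch": epoch, "theta": theta_avg.copy()}
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break

    w1, b1, w2, b2 = unpack(best["theta"])
    return TrainedModel(
        input_dim=d,
        hidden_units=hidden_units,
        w1=w1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        activation=activation,
        history=history,
        best_epoch=int(best["epoch"]),
        seed=seed,
        manifest_hash=manifest_hash,
    )


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Predict ddG (kcal/mol) for a feature matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(f"feature dimension {X.shape[1]} != model input_dim {model.input_dim}")
    xs = (X - model.x_mean) / model.x_scale
    ys = _forward_std(model.w1, model.b1, model.w2, model.b2, xs, model.activation)
    return ys * model.y_scale + model.y_mean


def cross_validate(X: np.ndarray, y: np.ndarray, k: int = 10, seed: int = 0,
                   **train_kwargs) -> dict:
    """Seeded k-fold cross-validation; every sample predicted exactly once.

    Returns fold assignments, the pooled out-of-fold prediction vector and
    pooled metrics (Pearson r, Spearman rho, Kendall tau, sigma).
    """
    from . import evaluation

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [perm[i::k] for i in range(k)]
    pooled = np.full(n, np.nan)
    fold_metrics = []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        m = train(X[train_mask], y[train_mask], seed=seed + 1 + f, **train_kwargs)
        pred = predict(m, X[test_idx])
        pooled[test_idx] = pred
        if len(test_idx) >= 2:
            fold_metrics.append({
                "fold": f,
                "n": int(len(test_idx)),
                "pearson_r": evaluation.pearson(y[test_idx], pred),
                "sigma": evaluation.stderr_sigma(y[test_idx], pred),
            })
    report = evaluation.metrics_report(y, pooled)
    return {
        "folds": [idx.tolist() for idx in folds],
        "predictions": pooled,
        "fold_metrics": fold_metrics,
        "pooled": report,
    }


# ---------------------------------------------------------------------------
# Serialization (documented JSON text format)
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "format": "rinstab-model-v1",
        "input_dim": model.input_dim,
        "hidden_units": model.hidden_units,
        "activation": model.activation,
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2,
        "x_mean": model.x_mean.tolist(),
        "x_scale": model.x_scale.tolist(),
        "y_mean": model.y_mean,
        "y_scale": model.y_scale,
        "history": model.history,
        "best_epoch": model.best_epoch,
        "seed": model.seed,
        "manifest_hash": model.manifest_hash,
        "sign_convention": model.sign_convention,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path, expected_manifest_hash: str | None = None) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "rinstab-model-v1":
        raise ValueError("unrecognized model file format")
    if (expected_manifest_hash is not None
            and payload.get("manifest_hash") is not None
            and payload["manifest_hash"] != expected_manifest_hash):
        raise ValueError("manifest hash mismatch: model was trained with a different feature layout")
    return TrainedModel(
        input_dim=payload["input_dim"],
        hidden_units=payload["hidden_units"],
        w1=np.array(payload["w1"], dtype=float),
        b1=np.array(payload["b1"], dtype=float),
        w2=np.array(payload["w2"], dtype=float),
        b2=float(payload["b2"]),
        x_mean=np.array(payload["x_mean"], dtype=float),
        x_scale=np.array(payload["x_scale"], dtype=float),
        y_mean=float(payload["y_mean"]),
        y_scale=float(payload["y_scale"]),
        activation=payload["activation"],
        history=payload["history"],
        best_epoch=payload["best_epoch"],
        seed=payload["seed"],
        manifest_hash=payload.get("manifest_hash"),
        sign_convention=payload.get("sign_convention", "positive_destabilizing"),
    )
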