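"""log P regression on scattering features.

A fully-connected ReLU network trained with Adam on mean-squared error,
with inverted dropout on hidden activations, mini-batches of 256, and a
step learning-rate schedule: lr(e) = lr_init * lr_factor^floor(e/lr_step)
(0.005 halved every 15 epochs by default, at most 400 epochs, no early
stopping).  Features are standardized per column before the network;
zero-variance columns (e.g. one-hot channels absent from a curated subset)
map to exactly 0.  Model selection is a full grid search over
{2,3,4,5} hidden layers x {300,400,500} units x {0.2,0.4} dropout under
5-fold cross-validation on validation MSE, the standardizer refitted
inside each fold on the training folds only.

The trainer is implemented directly on numpy arrays so that a fixed
``random_state`` reproduces final weights bit-for-bit; it follows the
scikit-learn estimator contract and composes with Pipeline /
cross-validation utilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.model_selection import KFold, ParameterGrid
from sklearn.preprocessing import StandardScaler
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

#: Hyperparameter grid of the reference training protocol.
DEFAULT_GRID = {
    "hidden_layers": [2, 3, 4, 5],
    "hidden_size": [300, 400, 500],
    "dropout": [0.2, 0.4],
}

#: Small grid (2x2x1) for resource-bounded model selection.
REDUCED_GRID = {
    "hidden_layers": [2, 3],
    "hidden_size": [300, 400],
    "dropout": [0.2],
}


class TrainingDivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class EvalMetrics:
    """Regression metrics; rmse >= mae >= 0 always."""

    rmse: float
    mae: float
    r2: float          # squared Pearson correlation
    r2_cod: float      # coefficient of determination


def evaluate(predictions, observed) -> EvalMetrics:
    """RMSE, MAE, and both r-squared conventions for a prediction set."""
    p = np.asarray(predictions, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size < 2:
        raise ValueError("need at least 2 prediction/observation pairs")
    err = p - o
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.std(p) == 0 or np.std(o) == 0:
        pearson2 = 0.0
    else:
        pearson2 = float(np.corrcoef(p, o)[0, 1] ** 2)
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    cod = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return EvalMetrics(rmse=rmse, mae=mae, r2=pearson2, r2_cod=cod)


def standardize_fit(X) -> StandardScaler:
    """Per-column standardizer; zero-variance columns transform to 0."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    scaler = StandardScaler().fit(X)
    # sklearn sets scale_=1 for zero-variance columns, so centered values
    # map to exactly 0; record which columns were degenerate.
    scaler.zero_variance_mask_ = scaler.var_ == 0
    return scaler


class LogPRegressor(BaseEstimator, RegressorMixin):
    """MLP regressor over standardized scattering features.

    Parameters mirror the reference training protocol; see module
    docstring.  Fitted attributes: ``scaler_``, ``coefs_``,
    ``intercepts_``, ``loss_curve_``, ``lr_schedule_``,
    ``n_features_in_``.
    """

    def __init__(self, hidden_layers=3, hidden_size=400, dropout=0.2,
                 lr_init=0.005, lr_factor=0.5, lr_step=15,
                 batch_size=256, max_epochs=400, standardize=True,
                 random_state=None):
        self.hidden_layers = hidden_layers
        self.hidden_size = hidden_size
        self.dropout = dropout
        self.lr_init = lr_init
        self.lr_factor = lr_factor
        self.lr_step = lr_step
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.standardize = standardize
        self.random_state = random_state

    # -- forward/backward ------------------------------------------------
    def _init_weights(self, n_in, rng):
        sizes = [n_in] + [self.hidden_size] * self.hidden_layers + [1]
        coefs, intercepts = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            std = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
            coefs.append(rng.normal(0.0, std, size=(fan_in, fan_out)))
            intercepts.append(np.zeros(fan_out))
        # zero-init the readout so the model starts at the target mean
        # (set in fit) instead of a random He-scale projection
        coefs[-1][:] = 0.0
        return coefs, intercepts

    def _forward(self, X, coefs, intercepts, rng=None):
        """Returns (prediction, activations, dropout masks)."""
        a = X
        acts, masks = [X], []
        L = len(coefs)
        for l in range(L - 1):
            z = a @ coefs[l] + intercepts[l]
            a = np.maximum(z, 0.0)
            if rng is not None and self.dropout > 0:
                mask = (rng.uniform(size=a.shape) >= self.dropout) / (
                    1.0 - self.dropout
                )
                a = a * mask
            else:
                mask = None
            masks.append(mask)
            acts.append(a)
        out = (a @ coefs[-1] + intercepts[-1]).ravel()
        return out, acts, masks

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        X = X.astype(np.float64)
        y = y.astype(np.float64)
        rng = check_random_state(self.random_state)

        if self.standardize:
            self.scaler_ = standardize_fit(X)
            X = self.scaler_.transform(X)
        else:
            self.scaler_ = None

        n, d = X.shape
        coefs, intercepts = self._init_weights(d, rng)
        # start the output bias at the target mean: the step-decayed Adam
        # schedule bounds total parameter displacement, so a centered start
        # removes an offset the optimizer would otherwise spend steps on
        intercepts[-1][:] = float(np.mean(y))
        m_c = [np.zeros_like(w) for w in coefs]
        v_c = [np.zeros_like(w) for w in coefs]
        m_i = [np.zeros_like(b) for b in intercepts]
        v_i = [np.zeros_like(b) for b in intercepts]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        self.loss_curve_, self.lr_schedule_ = [], []

        for epoch in range(self.max_epochs):
            lr = self.lr_init * self.lr_factor ** (epoch // self.lr_step)
            self.lr_schedule_.append(lr)
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                out, acts, masks = self._forward(xb, coefs, intercepts, rng)
                err = out - yb
                loss = np.mean(err**2)
                epoch_loss += loss * len(idx)
                if not np.isfinite(loss):
                    raise TrainingDivergenceError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                # backprop (MSE, ReLU, inverted dropout)
                grad = (2.0 / len(idx)) * err[:, None]
                grads_c = [None] * len(coefs)
                grads_i = [None] * len(coefs)
                for l in range(len(coefs) - 1, -1, -1):
                    grads_c[l] = acts[l].T @ grad
                    grads_i[l] = grad.sum(axis=0)
                    if l > 0:
                        grad = grad @ coefs[l].T
                        if masks[l - 1] is not None:
                            grad = grad * masks[l - 1]
                        grad = grad * (acts[l] > 0)
                # Adam update
                t += 1
                corr1 = 1 - beta1**t
                corr2 = 1 - beta2**t
                for l in range(len(coefs)):
                    for p, g, m, v in (
                        (coefs[l], grads_c[l], m_c[l], v_c[l]),
                        (intercepts[l], grads_i[l], m_i[l], v_i[l]),
                    ):
                        m *= beta1
                        m += (1 - beta1) * g
                        v *= beta2
                        v += (1 - beta2) * g**2
                        p -= lr * (m / corr1) / (np.sqrt(v / corr2) + eps)
            self.loss_curve_.append(epoch_loss / n)

        self.coefs_, self.intercepts_ = coefs, intercepts
        self.n_features_in_ = d
        return self

    def predict(self, X):
        check_is_fitted(self, "coefs_")
        X = check_array(X).astype(np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.n_features_in_} (feature layout mismatch)"
            )
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        out, _, _ = self._forward(X, self.coefs_, self.intercepts_, rng=None)
        return out


def grid_search_cv(X, y, param_grid=None, cv_folds=5, random_state=0,
                   **fit_params):
    """Exhaustive grid search with k-fold CV on validation MSE.

    The standardizer lives inside :class:`LogPRegressor`, so each fold's
    scaling is fitted on its training folds only.  Ties break toward fewer
    layers, then smaller width (the grid is walked in that order and only
    strict improvements replace the incumbent).

    Returns (best fitted model on all data, best params, results DataFrame).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if param_grid is None:
        param_grid = DEFAULT_GRID
    if X.shape[0] < cv_folds:
        raise ValueError(f"need at least {cv_folds} rows for {cv_folds}-fold CV")

    points = sorted(
        ParameterGrid(param_grid),
        key=lambda p: (p.get("hidden_layers", 0), p.get("hidden_size", 0),
                       p.get("dropout", 0)),
    )
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=random_state)
    splits = list(kf.split(X))
    base = LogPRegressor(random_state=random_state, **fit_params)

    rows, best = [], None
    for params in points:
        fold_mse = []
        for train_idx, val_idx in splits:
            model = clone(base).set_params(**params)
            model.fit(X[train_idx], y[train_idx])
            pred = model.predict(X[val_idx])
            fold_mse.append(float(np.mean((pred - y[val_idx]) ** 2)))
        mean_mse = float(np.mean(fold_mse))
        rows.append({**params, "mean_val_mse": mean_mse,
                     "fold_mse": fold_mse})
        if best is None or mean_mse < best[1]:
            best = (params, mean_mse)

    best_params, _ = best
    final = clone(base).set_params(**best_params).fit(X, y)
    return final, best_params, pd.DataFrame(rows)


# -- model persistence ----------------------------------------------------

def save_model(model: LogPRegressor, path, metadata=None) -> None:
    """Serialize a fitted model (weights + standardizer + metadata) as JSON."""
    check_is_fitted(model, "coefs_")
    payload = {
        "params": model.get_params(),
        "coefs": [w.tolist() for w in model.coefs_],
        "intercepts": [b.tolist() for b in model.intercepts_],
        "n_features_in": model.n_features_in_,
        "scaler": None,
        "metadata": metadata or {},
    }
    if model.scaler_ is not None:
        payload["scaler"] = {
            "mean": model.scaler_.mean_.tolist(),
            "scale": model.scaler_.scale_.tolist(),
            "var": model.scaler_.var_.tolist(),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> tuple[LogPRegressor, dict]:
    """Inverse of :func:`save_model`; returns (model, metadata)."""
    with open(path) as fh:
        payload = json.load(fh)
    model = LogPRegressor(**payload["params"])
    model.coefs_ = [np.asarray(w) for w in payload["coefs"]]
    model.intercepts_ = [np.asarray(b) for b in payload["intercepts"]]
    model.n_features_in_ = payload["n_features_in"]
    if payload["scaler"] is not None:
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(payload["scaler"]["mean"])
        scaler.scale_ = np.asarray(payload["scaler"]["scale"])
        scaler.var_ = np.asarray(payload["scaler"]["var"])
        scaler.n_features_in_ = len(scaler.mean_)
        scaler.with_mean = scaler.with_std = True
        model.scaler_ = scaler
    else:
        model.scaler_ = None
    return model, payload["metadata"]
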