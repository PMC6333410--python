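"""Densely connected feed-forward regressor (numpy, manual backprop).

Architecture fixed to the ensemble's neural base learner: five hidden
layers of 100 units, each Linear -> BatchNorm -> ReLU -> Dropout, then a
linear output. Trained with Adam on mean-squared error; targets are
internally standardised for stable optimisation and de-standardised at
prediction. Batch norm uses batch statistics in training and exponential
running averages at inference; dropout is inverted (activations rescaled at
train time) so inference needs no correction.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["DenseDropoutRegressor"]

_EPS = 1e-5


class DenseDropoutRegressor(RegressorMixin, BaseEstimator):
    """5x100 dense network with batch normalisation and dropout.

    Parameters
    ----------
    hidden_units : width of each of the five hidden layers.
    dropout : dropout probability between layers (0.2 default).
    epochs, batch_size, learning_rate : Adam training budget.
    bn_momentum : running-statistics momentum for batch norm.
    random_state : seed for init, shuffling and dropout masks.
    """

    N_HIDDEN_LAYERS = 5

    def __init__(self, hidden_units: int = 100, dropout: float = 0.2,
                 epochs: int = 60, batch_size: int = 128,
                 learning_rate: float = 1e-3, bn_momentum: float = 0.9,
                 random_state: int = 0):
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.bn_momentum = bn_momentum
        self.random_state = random_state

    # -- parameter helpers ---------------------------------------------------
    def _init_params(self, d_in: int, rng: np.random.Generator):
        dims = [d_in] + [self.hidden_units] * self.N_HIDDEN_LAYERS
        self._W, self._b, self._gamma, self._beta = [], [], [], []
        self._run_mean, self._run_var = [], []
        for a, b in zip(dims[:-1], dims[1:]):
            self._W.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
            self._b.append(np.zeros(b))
            self._gamma.append(np.ones(b))
            self._beta.append(np.zeros(b))
            self._run_mean.append(np.zeros(b))
            self._run_var.append(np.ones(b))
        self._Wo = rng.normal(0.0, np.sqrt(2.0 / dims[-1]), size=(dims[-1], 1))
        self._bo = np.zeros(1)

    def _params(self):
        return self._W + self._b + self._gamma + self._beta + [self._Wo, self._bo]

    # -- forward / backward --------------------------------------------------
    def _forward_train(self, X, rng):
        cache = []
        h = X
        keep = 1.0 - self.dropout
        for i in range(self.N_HIDDEN_LAYERS):
            z = h @ self._W[i] + self._b[i]
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            inv = 1.0 / np.sqrt(var + _EPS)
            zhat = (z - mu) * inv
            a = self._gamma[i] * zhat + self._beta[i]
            relu_mask = a > 0
            a = a * relu_mask
            drop_mask = (rng.random(a.shape) < keep) / keep if self.dropout > 0 else 1.0
            out = a * drop_mask
            m = self.bn_momentum
            self._run_mean[i] = m * self._run_mean[i] + (1 - m) * mu
            self._run_var[i] = m * self._run_var[i] + (1 - m) * var
            cache.append((h, zhat, inv, relu_mask, drop_mask))
            h = out
        yhat = (h @ self._Wo + self._bo).ravel()
        return yhat, h, cache

    def _backward(self, X, yhat, y, h_last, cache):
        m = len(y)
        grads_W = [None] * self.N_HIDDEN_LAYERS
        grads_b = [None] * self.N_HIDDEN_LAYERS
        grads_g = [None] * self.N_HIDDEN_LAYERS
        grads_be = [None] * self.N_HIDDEN_LAYERS
        dy = (2.0 / m) * (yhat - y)[:, None]
        gWo = h_last.T @ dy
        gbo = dy.sum(axis=0)
        dh = dy @ self._Wo.T
        for i in reversed(range(self.N_HIDDEN_LAYERS)):
            h_in, zhat, inv, relu_mask, drop_mask = cache[i]
            da = dh * drop_mask * relu_mask
            grads_g[i] = (da * zhat).sum(axis=0)
            grads_be[i] = da.sum(axis=0)
            dzhat = da * self._gamma[i]
            n = da.shape[0]
            dz = (inv / n) * (n * dzhat - dzhat.sum(axis=0)
                              - zhat * (dzhat * zhat).sum(axis=0))
            grads_W[i] = h_in.T @ dz
            grads_b[i] = dz.sum(axis=0)
            dh = dz @ self._W[i].T
        return grads_W + grads_b + grads_g + grads_be + [gWo, gbo]

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.random_state)
        self._x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0)
        self._x_sd = np.where(x_sd > 1e-12, x_sd, 1.0)
        self._y_mean = float(y.mean())
        self._y_sd = float(y.std()) or 1.0
        Xs = (X - self._x_mean) / self._x_sd
        ys = (y - self._y_mean) / self._y_sd

        self._init_params(Xs.shape[1], rng)
        params = self._params()
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(ys)
        bs = min(self.batch_size, n)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                if len(idx) < 2:  # batch norm needs > 1 row
                    continue
                yhat, h_last, cache = self._forward_train(Xs[idx], rng)
                grads = self._backward(Xs[idx], yhat, ys[idx], h_last, cache)
                step += 1
                lr = self.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
                for p, g, mt, vt in zip(params, grads, m_t, v_t):
                    mt *= b1
                    mt += (1 - b1) * g
                    vt *= b2
                    vt += (1 - b2) * g * g
                    p -= lr * mt / (np.sqrt(vt) + eps)
        self._calibrate_batchnorm(Xs)
        self.n_features_in_ = Xs.shape[1]
        self.is_fitted_ = True
        return self

    def _calibrate_batchnorm(self, Xs):
        """Replace running batch-norm statistics with exact statistics of the
        full training set (one deterministic forward pass, no dropout)."""
        h = Xs
        for i in range(self.N_HIDDEN_LAYERS):
            z = h @ self._W[i] + self._b[i]
            self._run_mean[i] = z.mean(axis=0)
            self._run_var[i] = z.var(axis=0)
            zhat = (z - self._run_mean[i]) / np.sqrt(self._run_var[i] + _EPS)
            h = np.maximum(self._gamma[i] * zhat + self._beta[i], 0.0)

    def predict(self, X):
        check_is_fitted(self, "is_fitted_")
        h = (np.asarray(X, dtype=float) - self._x_mean) / self._x_sd
        for i in range(self.N_HIDDEN_LAYERS):
            z = h @ self._W[i] + self._b[i]
            zhat = (z - self._run_mean[i]) / np.sqrt(self._run_var[i] + _EPS)
            a = self._gamma[i] * zhat + self._beta[i]
            h = np.maximum(a, 0.0)
        ys = (h @ self._Wo + self._bo).ravel()
        return ys * self._y_sd + self._y_mean
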