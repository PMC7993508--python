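"""Affinity regressors and evaluation metrics.

Two learners are provided in a Model/Results style: construct the model
from labeled datasets, call :meth:`fit`, and work with the returned
results object (predictions, metrics, ``summary()``).

* :class:`RandomForestAffinity` — bagged regression trees (scikit-learn
  backend); the prediction is the mean over trees.  The grid the package
  is tuned over is ``n_estimators`` in {100..500} and ``max_features``
  in {"auto" (all features), "sqrt"}.
* :class:`DeepAffinityNetwork` — a dense stack
  input -> 400 -> 200 -> 100 -> 1 with batch normalization, ReLU and
  dropout after every hidden layer, trained by minibatch SGD
  (learning rate 0.001, decay 1e-6, momentum 0.9) with L2 weight decay.
  After every epoch the validation composite loss

      LOSS = alpha * (1 - PCC) + (1 - alpha) * RMSE

  is computed and the weights of the epoch with the smallest validation
  LOSS are returned, which stops training before the over-fitting regime.
  The network is implemented directly on NumPy arrays; its parameter
  count is audited against :func:`count_dnn_parameters`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import LabeledDataset, Standardizer
from .fragments import FragmentDictionary

HIDDEN_UNITS = (400, 200, 100)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root of the mean squared prediction error."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute prediction error."""
    return float(np.mean(np.abs(np.asarray(y_pred) - np.asarray(y_true))))


def pcc(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and its two-sided p-value (t transform)."""
    r = stats.pearsonr(np.asarray(y_true, float), np.asarray(y_pred, float))
    return float(r.statistic), float(r.pvalue)


def spearman(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(stats.spearmanr(y_true, y_pred).statistic)


def composite_loss(pcc_value: float, rmse_value: float, alpha: float) -> float:
    """Model-selection loss: alpha*(1 - PCC) + (1 - alpha)*RMSE."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return alpha * (1.0 - pcc_value) + (1.0 - alpha) * rmse_value


@dataclass
class EvaluationReport:
    """Standard regression metrics for one prediction set."""

    rmse: float
    mae: float
    pcc: float | None
    p_value: float | None
    spearman: float | None
    n: int

    def to_dict(self) -> dict:
        return {
            "RMSE": self.rmse, "MAE": self.mae, "PCC": self.pcc,
            "p_value": self.p_value, "Spearman": self.spearman, "N": self.n,
        }

    def __str__(self) -> str:
        fmt = lambda v: "NA" if v is None else f"{v:.4g}"
        return (
            f"N={self.n}  RMSE={self.rmse:.4f}  MAE={self.mae:.4f}  "
            f"PCC={fmt(self.pcc)} (p={fmt(self.p_value)})  "
            f"Sp={fmt(self.spearman)}"
        )


def evaluation_report(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationReport:
    """Compute all metrics; correlations are absent when undefined
    (fewer than two points, or a constant vector)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    n = len(y_true)
    r = p = sp = None
    if n >= 2 and np.ptp(y_true) > 0 and np.ptp(y_pred) > 0:
        r, p = pcc(y_true, y_pred)
        sp = spearman(y_true, y_pred)
    return EvaluationReport(
        rmse=rmse(y_true, y_pred), mae=mae(y_true, y_pred),
        pcc=r, p_value=p, spearman=sp, n=n,
    )


def baseline_null(train: LabeledDataset, test: LabeledDataset) -> EvaluationReport:
    """Null model: predict the training-label mean for every test row."""
    pred = np.full(test.n, float(np.mean(train.y)))
    return evaluation_report(test.y, pred)


def count_dnn_parameters(input_dim: int) -> int:
    """Learning-parameter count of the dense 400/200/100 stack.

    Dense weights and biases plus four batch-norm parameters per hidden
    unit (scale, shift, running mean, running variance).
    """
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    dims = (input_dim, *HIDDEN_UNITS, 1)
    dense = sum(d_in * d_out + d_out for d_in, d_out in zip(dims, dims[1:]))
    batchnorm = 4 * sum(HIDDEN_UNITS)
    return dense + batchnorm


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters (the tuned grid is n_estimators in
    {100..500} and max_features in {"auto", "sqrt"})."""

    n_estimators: int = 100
    max_features: str = "auto"  # "auto" = all features; or "sqrt"
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_features not in ("auto", "sqrt"):
            raise ValueError('max_features must be "auto" or "sqrt"')


class RandomForestAffinity:
    """Bagged regression-tree model of binding affinity.

    Parameters
    ----------
    train : LabeledDataset
        Feature matrix and pKd/pKi labels.
    config : RFConfig, optional
        Ensemble size, feature sampling and seed.
    """

    def __init__(self, train: LabeledDataset, config: RFConfig | None = None):
        if train.n < 10:
            raise ValueError("need at least 10 training rows")
        self.train = train
        self.config = config or RFConfig()

    def fit(self) -> "RandomForestAffinityResults":
        import warnings

        from sklearn.ensemble import RandomForestRegressor

        if np.ptp(self.train.y) == 0:
            warnings.warn("constant training labels; the forest will predict "
                          "that constant everywhere")
        max_features = 1.0 if self.config.max_features == "auto" else "sqrt"
        forest = RandomForestRegressor(
            n_estimators=self.config.n_estimators,
            max_features=max_features,
            random_state=self.config.random_state,
        )
        forest.fit(self.train.X, self.train.y)
        return RandomForestAffinityResults(model=self, forest=forest)


@dataclass
class RandomForestAffinityResults:
    """Fitted forest: predictions are the mean over tree predictions."""

    model: RandomForestAffinity
    forest: object

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict(np.asarray(X, dtype=float))

    def evaluate(self, test: LabeledDataset) -> EvaluationReport:
        _check_compatible(self.model.train, test)
        return evaluation_report(test.y, self.predict(test.X))

    def feature_importances(self) -> pd.Series:
        names = self.model.train.feature_names or None
        return pd.Series(self.forest.feature_importances_, index=names)

    def summary(self) -> str:
        cfg = self.model.config
        rep = evaluation_report(self.model.train.y, self.predict(self.model.train.X))
        top = self.feature_importances().sort_values(ascending=False).head(10)
        lines = [
            "Random-forest affinity model",
            "============================",
            f"feature set:   {self.model.train.feature_set} "
            f"(d={self.model.train.X.shape[1]})",
            f"n_estimators:  {cfg.n_estimators}   max_features: {cfg.max_features}"
            f"   seed: {cfg.random_state}",
            f"training fit:  {rep}",
            "top feature importances:",
        ]
        lines += [f"  {name}: {val:.4f}" for name, val in top.items()]
        return "\n".join(lines)


def _check_compatible(train: LabeledDataset, test: LabeledDataset) -> None:
    if train.feature_set != test.feature_set:
        raise ValueError(
            f"feature-set mismatch: model trained on {train.feature_set!r}, "
            f"evaluation data is {test.feature_set!r}")
    if (train.dictionary is not None and test.dictionary is not None
            and train.dictionary.sha256() != test.dictionary.sha256()):
        raise ValueError("fragment-dictionary mismatch between model and data")
    if train.X.shape[1] != test.X.shape[1]:
        raise ValueError("feature dimension mismatch")


def train_rf(train: LabeledDataset, config: RFConfig | None = None
             ) -> RandomForestAffinityResults:
    """Functional wrapper over RandomForestAffinity(...).fit()."""
    return RandomForestAffinity(train, config).fit()


# ---------------------------------------------------------------------------
# deep network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DNNConfig:
    """Deep-network hyperparameters.  The hidden stack is fixed at
    400/200/100 units; dropout, alpha and batch size are the tuned knobs."""

    dropout: float = 0.1
    alpha: float = 0.7
    batch_size: int = 64
    learning_rate: float = 0.001
    decay: float = 1e-6
    momentum: float = 0.9
    l2_penalty: float = 1e-4
    max_epochs: int = 100
    patience: int | None = None  # epochs without improvement; None = run all
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class _BatchNorm:
    """Per-feature batch normalization with running statistics."""

    def __init__(self, dim: int, momentum: float = 0.99, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        cache = (xhat, inv)
        return self.gamma * xhat + self.beta, cache

    def backward(self, dout: np.ndarray, cache) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xhat, inv = cache
        m = dout.shape[0]
        dgamma = (dout * xhat).sum(axis=0)
        dbeta = dout.sum(axis=0)
        dxhat = dout * self.gamma
        dx = inv / m * (
            m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        return dx, dgamma, dbeta


class _DenseNet:
    """The 400/200/100 dense stack on raw NumPy arrays."""

    def __init__(self, input_dim: int, dropout: float, rng: np.random.Generator):
        dims = (input_dim, *HIDDEN_UNITS, 1)
        self.W = [
            rng.normal(0.0, math.sqrt(2.0 / d_in), size=(d_in, d_out))
            for d_in, d_out in zip(dims, dims[1:])
        ]
        self.b = [np.zeros(d_out) for d_out in dims[1:]]
        self.bn = [_BatchNorm(d) for d in HIDDEN_UNITS]
        self.dropout = dropout
        self.rng = rng

    def n_parameters(self) -> int:
        n = sum(w.size for w in self.W) + sum(b.size for b in self.b)
        for bn in self.bn:
            n += bn.gamma.size + bn.beta.size
            n += bn.running_mean.size + bn.running_var.size
        return n

    def forward(self, x: np.ndarray, training: bool):
        caches = []
        for i, bn in enumerate(self.bn):
            z = x @ self.W[i] + self.b[i]
            h, bn_cache = bn.forward(z, training)
            a = np.maximum(h, 0.0)
            if training and self.dropout > 0:
                mask = (self.rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                a_dropped = a * mask
            else:
                mask = None
                a_dropped = a
            caches.append((x, bn_cache, h, mask))
            x = a_dropped
        out = x @ self.W[-1] + self.b[-1]
        caches.append((x,))
        return out[:, 0], caches

    def backward(self, dout: np.ndarray, caches) -> list[tuple[np.ndarray, ...]]:
        """Returns per-layer gradients [(dW, db, dgamma, dbeta) ...]."""
        grads: list[tuple[np.ndarray, ...]] = [None] * len(self.W)
        d = dout[:, None]
        (x_last,) = caches[-1]
        grads[-1] = (x_last.T @ d, d.sum(axis=0))
        d = d @ self.W[-1].T
        for i in range(len(self.bn) - 1, -1, -1):
            x_in, bn_cache, h, mask = caches[i]
            if mask is not None:
                d = d * mask
            d = d * (h > 0)
            d, dgamma, dbeta = self.bn[i].backward(d, bn_cache)
            grads[i] = (x_in.T @ d, d.sum(axis=0), dgamma, dbeta)
            d = d @ self.W[i].T
        return grads

    def get_weights(self) -> list[np.ndarray]:
        out = [w.copy() for w in self.W] + [b.copy() for b in self.b]
        for bn in self.bn:
            out += [bn.gamma.copy(), bn.beta.copy(),
                    bn.running_mean.copy(), bn.running_var.copy()]
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [w.copy() for w in weights[:k]]
        self.b = [b.copy() for b in weights[k:2 * k]]
        rest = weights[2 * k:]
        for i, bn in enumerate(self.bn):
            bn.gamma, bn.beta, bn.running_mean, bn.running_var = (
                a.copy() for a in rest[4 * i:4 * i + 4]
            )


class DeepAffinityNetwork:
    """Deep dense affinity model with composite-loss epoch selection.

    Features are standardized with the training-set mean/variance; the
    constants are stored on the results object and applied automatically
    at prediction time.
    """

    def __init__(
        self,
        train: LabeledDataset,
        valid: LabeledDataset,
        config: DNNConfig | None = None,
    ):
        if valid.n < 2:
            raise ValueError("validation set must have at least 2 rows")
        _check_compatible(train, valid)
        self.train = train
        self.valid = valid
        self.config = config or DNNConfig()

    def fit(self, verbose: bool = False) -> "DeepAffinityNetworkResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        scaler = Standardizer.fit(self.train.X)
        Xtr = scaler.transform(self.train.X)
        Xva = scaler.transform(self.valid.X)
        ytr, yva = self.train.y, self.valid.y

        net = _DenseNet(Xtr.shape[1], cfg.dropout, rng)
        velocity = None
        step = 0
        history = []
        best = (np.inf, -1, None)  # (valid loss, epoch, weights)

        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                if len(idx) < 2:  # batch statistics need >= 2 rows
                    continue
                xb, yb = Xtr[idx], ytr[idx]
                pred, caches = net.forward(xb, training=True)
                err = pred - yb
                if not np.all(np.isfinite(err)):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}, step {step}: "
                        "non-finite loss")
                grads = net.backward(err / len(idx), caches)
                params, gradlist = [], []
                for i in range(len(net.W)):
                    g = grads[i]
                    params += [net.W[i], net.b[i]]
                    gradlist += [g[0] + cfg.l2_penalty * net.W[i], g[1]]
                    if len(g) == 4:
                        params += [net.bn[i].gamma, net.bn[i].beta]
                        gradlist += [g[2], g[3]]
                if velocity is None:
                    velocity = [np.zeros_like(p) for p in params]
                lr = cfg.learning_rate / (1.0 + cfg.decay * step)
                for p, g, v in zip(params, gradlist, velocity):
                    v *= cfg.momentum
                    v -= lr * g
                    p += v
                step += 1

            tr_pred, _ = net.forward(Xtr, training=False)
            va_pred, _ = net.forward(Xva, training=False)
            tr_rmse = rmse(ytr, tr_pred)
            va_rmse = rmse(yva, va_pred)
            va_pcc = pcc(yva, va_pred)[0] if np.ptp(va_pred) > 0 else 0.0
            va_loss = composite_loss(va_pcc, va_rmse, cfg.alpha)
            history.append(
                {"epoch": epoch, "train_rmse": tr_rmse, "valid_rmse": va_rmse,
                 "valid_pcc": va_pcc, "valid_loss": va_loss}
            )
            if verbose:
                print(f"epoch {epoch:3d}  train RMSE {tr_rmse:.4f}  "
                      f"valid RMSE {va_rmse:.4f}  valid LOSS {va_loss:.4f}")
            if va_loss < best[0]:
                best = (va_loss, epoch, net.get_weights())
            elif cfg.patience is not None and epoch - best[1] >= cfg.patience:
                break

        net.set_weights(best[2])
        return DeepAffinityNetworkResults(
            model=self, net=net, scaler=scaler,
            history=pd.DataFrame(history), best_epoch=best[1],
        )


@dataclass
class DeepAffinityNetworkResults:
    """Fitted deep network restored to its best-validation-loss epoch."""

    model: DeepAffinityNetwork
    net: _DenseNet
    scaler: Standardizer
    history: pd.DataFrame
    best_epoch: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        pred, _ = self.net.forward(self.scaler.transform(np.asarray(X, float)),
                                   training=False)
        return pred

    def evaluate(self, test: LabeledDataset) -> EvaluationReport:
        _check_compatible(self.model.train, test)
        return evaluation_report(test.y, self.predict(test.X))

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def summary(self) -> str:
        cfg = self.model.config
        row = self.history.iloc[self.best_epoch]
        return "\n".join([
            "Deep affinity network",
            "=====================",
            f"architecture:  input({self.model.train.X.shape[1]}) -> 400 -> "
            "200 -> 100 -> 1 (BN+ReLU+dropout per hidden layer)",
            f"parameters:    {self.n_parameters:,}",
            f"alpha: {cfg.alpha}  dropout: {cfg.dropout}  "
            f"batch: {cfg.batch_size}  seed: {cfg.seed}",
            f"selected epoch {self.best_epoch} of {len(self.history)} "
            f"(valid LOSS {row['valid_loss']:.4f}, "
            f"valid RMSE {row['valid_rmse']:.4f}, "
            f"valid PCC {row['valid_pcc']:.4f})",
        ])


def train_dnn(
    train: LabeledDataset, valid: LabeledDataset, config: DNNConfig | None = None
) -> DeepAffinityNetworkResults:
    """Functional wrapper over DeepAffinityNetwork(...).fit()."""
    return DeepAffinityNetwork(train, valid, config).fit()
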