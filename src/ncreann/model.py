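"""Neural-network nMVAR estimation: model order selection, MLP training
under incremental back-propagation, prediction and fit metrics.

The predictor f of the nMVAR model x(n) = f(x_p) + sigma(n) is realized by
a single-hidden-layer perceptron (default 10 tanh units) trained with
incremental (per-sample) gradient-descent error back-propagation with
momentum, an adaptive learning rate, and early stopping on a validation
block.  A permuted n-fold scheme rotates a held-out test block across
folds (80/10/10 at the default 10 folds), yielding one model per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._train import ACT_IDENTITY, ACT_TANH, epoch_pass
from .containers import RegressionSampleSet, TimeSeriesMatrix, ValidationError
from .prep import build_regression_samples

ACTIVATIONS = {"tanh": ACT_TANH, "identity": ACT_IDENTITY}


class TrainingDivergedError(RuntimeError):
    """Raised when incremental training produces non-finite weights or error."""


@dataclass
class NMVARConfig:
    """Hyperparameters of the nMVAR network and its training protocol.

    Defaults follow the analysis protocol: order p = 5, one hidden layer of
    10 units, weights initialized uniformly in [-0.5, 0.5], incremental EBP
    with momentum and an adaptive learning rate, early stopping, and a
    10-fold permuted cross-validation with an 80/10/10 split.
    """

    order: int = 5
    hidden_units: int = 10
    activation: str = "tanh"
    init_range: tuple[float, float] = (-0.5, 0.5)
    learning_rate: float = 0.01
    momentum: float = 0.9
    lr_up: float = 1.05
    lr_down: float = 0.7
    lr_max: float = 0.05
    max_epochs: int = 500
    patience: int = 20
    n_folds: int = 10
    min_rows: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order < 1 or self.hidden_units < 1:
            raise ValidationError("order and hidden_units must be >= 1")
        if not 0.0 <= self.momentum < 1.0:
            raise ValidationError("momentum must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.activation not in ACTIVATIONS:
            raise ValidationError(f"unknown activation {self.activation!r}")
        lo, hi = self.init_range
        if not lo < hi:
            raise ValidationError("init_range must be an increasing pair")


@dataclass
class NMVARModel:
    """A trained realization of f, plus the standardization applied to its inputs."""

    hidden_weights: np.ndarray   # (H, M*p)
    hidden_biases: np.ndarray    # (H,)
    output_weights: np.ndarray   # (M, H)
    output_biases: np.ndarray    # (M,)
    activation: str
    p: int
    n_channels: int
    channel_mean: np.ndarray     # (M,) standardization fitted on the training rows
    channel_sd: np.ndarray       # (M,)
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        h, d = self.hidden_weights.shape
        m = self.output_weights.shape[0]
        if d != self.n_channels * self.p or self.output_weights.shape[1] != h:
            raise ValidationError("model weight dimensions are inconsistent")
        for arr in (self.hidden_weights, self.hidden_biases, self.output_weights, self.output_biases):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("model weights must be finite")

    def standardize_inputs(self, inputs: np.ndarray) -> np.ndarray:
        """Map raw lag-vector rows into the model's standardized input space."""
        tiled_mean = np.tile(self.channel_mean, self.p)
        tiled_sd = np.tile(self.channel_sd, self.p)
        return (np.asarray(inputs, dtype=float) - tiled_mean) / tiled_sd

    def standardize_targets(self, targets: np.ndarray) -> np.ndarray:
        return (np.asarray(targets, dtype=float) - self.channel_mean) / self.channel_sd


def predict(model: NMVARModel, inputs: np.ndarray) -> np.ndarray:
    """Evaluate the network on (standardized) input rows of length M*p."""
    x = np.atleast_2d(np.asarray(inputs, dtype=float))
    if x.shape[1] != model.hidden_weights.shape[1]:
        raise ValidationError(
            f"input row length {x.shape[1]} != M*p = {model.hidden_weights.shape[1]}"
        )
    pre = x @ model.hidden_weights.T + model.hidden_biases
    h = np.tanh(pre) if model.activation == "tanh" else pre
    return h @ model.output_weights.T + model.output_biases


def compute_metrics(targets: np.ndarray, predictions: np.ndarray) -> tuple[float, float]:
    """Pooled R^2 and MSE over all channels.

    MSE is the mean squared residual pooled over channels; R^2 pools the
    residual and total sums of squares around the per-channel target means.
    """
    y = np.atleast_2d(np.asarray(targets, dtype=float))
    yhat = np.atleast_2d(np.asarray(predictions, dtype=float))
    if y.shape != yhat.shape:
        raise ValidationError("targets and predictions must have equal shapes")
    if y.shape[0] < 2:
        raise ValidationError("need at least 2 rows to compute fit metrics")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean(axis=0)) ** 2))
    if ss_tot == 0:
        raise ValidationError("targets have zero variance; R^2 undefined")
    mse = ss_res / y.size
    r2 = 1.0 - ss_res / ss_tot
    return r2, mse


@dataclass
class FitMetrics:
    """Per-fold fit diagnostics for a trained nMVAR network."""

    table: pd.DataFrame  # fold, r2_train, mse_train, r2_val, mse_val, r2_test, mse_test, epochs
    train_error_history: list[np.ndarray] = field(default_factory=list)

    @property
    def min_r2_test(self) -> float:
        return float(self.table["r2_test"].min())

    @property
    def max_mse_test(self) -> float:
        return float(self.table["mse_test"].max())

    @property
    def max_generalization_gap(self) -> float:
        return float((self.table["r2_train"] - self.table["r2_test"]).abs().max())


def _fold_splits(n_rows: int, n_folds: int, rng: np.random.Generator):
    """One master permutation; the test block rotates, validation is the
    next block, the remainder trains.  Test blocks are disjoint and
    exhaustive across folds."""
    perm = rng.permutation(n_rows)
    blocks = np.array_split(perm, n_folds)
    for k in range(n_folds):
        test = blocks[k]
        val = blocks[(k + 1) % n_folds]
        train = np.concatenate([blocks[j] for j in range(n_folds) if j not in (k, (k + 1) % n_folds)])
        yield train, val, test


def _forward_mse(X, Y, W1, b1, W2, b2, act_id) -> float:
    pre = X @ W1.T + b1
    h = np.tanh(pre) if act_id == ACT_TANH else pre
    resid = h @ W2.T + b2 - Y
    return float(np.mean(resid**2))


def fit_ncreann(
    samples: RegressionSampleSet, config: NMVARConfig
) -> tuple[list[NMVARModel], FitMetrics]:
    """Train one network per fold under the incremental EBP protocol.

    Per fold: rows are split into train/validation/test blocks (the test
    block rotates across folds under one seeded permutation), channels are
    standardized on the training rows only, weights start uniform in
    ``init_range``, and every sample triggers a gradient update with
    momentum.  After each epoch the training error decides the adaptive
    learning rate: an improvement multiplies eta by ``lr_up``; an increase
    rejects the epoch (weights and momentum restored) and multiplies eta by
    ``lr_down``.  Training stops when the validation error has not improved
    for ``patience`` epochs or at ``max_epochs``; the best-validation
    weights are restored.
    """
    n = samples.n_rows
    m = samples.n_channels
    if samples.p != config.order:
        raise ValidationError(
            f"sample set was built with p = {samples.p} but config.order = {config.order}"
        )
    if n < config.min_rows:
        raise ValidationError(f"{n} regression rows < minimum {config.min_rows} to attempt training")
    if config.n_folds < 3:
        raise ValidationError("n_folds must be >= 3 so a training block remains")
    h = config.hidden_units
    d = m * config.order
    n_params = h * (d + 1) + m * (h + 1)
    if n < 10 * n_params:
        warnings.warn(
            f"{n} rows < 10x parameter count ({n_params}); fits may be unstable",
            stacklevel=2,
        )
    act_id = ACTIVATIONS[config.activation]
    rng = np.random.default_rng(config.seed)
    models: list[NMVARModel] = []
    rows = []
    histories: list[np.ndarray] = []
    lo, hi_ = config.init_range
    for fold, (tr, va, te) in enumerate(_fold_splits(n, config.n_folds, rng)):
        fold_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        mean = samples.targets[tr].mean(axis=0)
        sd = samples.targets[tr].std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValidationError("a channel is constant on the training rows")
        tiled_mean, tiled_sd = np.tile(mean, config.order), np.tile(sd, config.order)
        X = (samples.inputs - tiled_mean) / tiled_sd
        Y = (samples.targets - mean) / sd
        Xtr, Ytr = np.ascontiguousarray(X[tr]), np.ascontiguousarray(Y[tr])
        Xva, Yva = X[va], Y[va]

        W1 = fold_rng.uniform(lo, hi_, size=(h, d))
        b1 = fold_rng.uniform(lo, hi_, size=h)
        W2 = fold_rng.uniform(lo, hi_, size=(m, h))
        b2 = fold_rng.uniform(lo, hi_, size=m)
        vW1, vb1 = np.zeros_like(W1), np.zeros_like(b1)
        vW2, vb2 = np.zeros_like(W2), np.zeros_like(b2)

        lr = config.learning_rate
        prev_err = _forward_mse(Xtr, Ytr, W1, b1, W2, b2, act_id)
        best_val = np.inf
        best_weights = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
        wait = 0
        accepted_errors = [prev_err]
        order = np.arange(Xtr.shape[0])
        for epoch in range(config.max_epochs):
            fold_rng.shuffle(order)
            snapshot = (W1.copy(), b1.copy(), W2.copy(), b2.copy(),
                        vW1.copy(), vb1.copy(), vW2.copy(), vb2.copy())
            epoch_pass(Xtr, Ytr, order, W1, b1, W2, b2, vW1, vb1, vW2, vb2,
                       lr, config.momentum, act_id)
            err = _forward_mse(Xtr, Ytr, W1, b1, W2, b2, act_id)
            if not np.isfinite(err) or err > 1e12:
                raise TrainingDivergedError(
                    f"fold {fold}: training error diverged at epoch {epoch} (err = {err})"
                )
            if err > prev_err:
                # reject: restore weights and momentum, shrink the step
                W1, b1, W2, b2, vW1, vb1, vW2, vb2 = (a.copy() for a in snapshot)
                lr = max(lr * config.lr_down, 1e-8)
            else:
                prev_err = err
                accepted_errors.append(err)
                lr = min(lr * config.lr_up, config.lr_max)
            val_err = _forward_mse(Xva, Yva, W1, b1, W2, b2, act_id)
            if val_err < best_val * (1.0 - 1e-9):
                best_val = val_err
                best_weights = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
                wait = 0
            else:
                wait += 1
                if wait >= config.patience:
                    break
        W1, b1, W2, b2 = best_weights
        model = NMVARModel(
            hidden_weights=W1, hidden_biases=b1, output_weights=W2, output_biases=b2,
            activation=config.activation, p=config.order, n_channels=m,
            channel_mean=mean, channel_sd=sd, channel_labels=list(samples.channel_labels),
        )
        models.append(model)
        row = {"fold": fold}
        for name, idx in (("train", tr), ("val", va), ("test", te)):
            r2, mse = compute_metrics(Y[idx], predict(model, X[idx]))
            row[f"r2_{name}"] = r2
            row[f"mse_{name}"] = mse
        row["epochs"] = epoch + 1
        rows.append(row)
        histories.append(np.asarray(accepted_errors))
    metrics = FitMetrics(table=pd.DataFrame(rows), train_error_history=histories)
    return models, metrics


@dataclass
class OrderSelection:
    """AIC/BIC table over candidate orders and the two selected orders."""

    table: pd.DataFrame  # p, aic, bic, logdet_sigma
    aic_order: int
    bic_order: int

    @property
    def selected(self) -> int:
        """Pipeline default: the (more parsimonious) Schwartz/BIC choice."""
        return self.bic_order


def _ols_var(samples: RegressionSampleSet) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares VAR fit on lag rows: coefficients (M*p, M) and residuals."""
    coef, *_ = np.linalg.lstsq(samples.inputs, samples.targets, rcond=None)
    resid = samples.targets - samples.inputs @ coef
    return coef, resid


def ols_var_coefficients(samples: RegressionSampleSet) -> np.ndarray:
    """Per-lag VAR coefficient matrices A_tau (tau, j, i) by least squares."""
    coef, _ = _ols_var(samples)
    m = samples.n_channels
    return coef.reshape(samples.p, m, m).transpose(0, 2, 1)


def select_model_order(series: TimeSeriesMatrix, p_max: int) -> OrderSelection:
    """Linear VAR order selection by the Akaike and Schwartz criteria.

    Fits ordinary-least-squares VAR(p) for p = 1..p_max on a common sample
    (targets valid at p_max, so criteria are comparable across orders) and
    scores AIC = ln det(Sigma) + 2 k / T and BIC = ln det(Sigma) +
    k ln(T) / T with k = p M^2 free coefficients.
    """
    m = series.n_channels
    t_total = series.n_samples
    if p_max < 1:
        raise ValidationError("p_max must be >= 1")
    if p_max >= t_total / (2 * m):
        raise ValidationError(f"p_max = {p_max} too large for L = {t_total}, M = {m}")
    full = build_regression_samples(series, p_max)
    t_eff = full.n_rows
    rows = []
    for p in range(1, p_max + 1):
        # columns 0..p*M-1 of the p_max lag rows are exactly the p-lag vectors
        sub = RegressionSampleSet(
            inputs=full.inputs[:, : p * m],
            targets=full.targets,
            p=p,
            source_sample_index=full.source_sample_index,
            channel_labels=full.channel_labels,
        )
        _, resid = _ols_var(sub)
        sigma = (resid.T @ resid) / t_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise ValidationError(f"residual covariance not positive definite at p = {p}")
        k = p * m * m
        rows.append(
            {
                "p": p,
                "logdet_sigma": logdet,
                "aic": logdet + 2.0 * k / t_eff,
                "bic": logdet + np.log(t_eff) * k / t_eff,
            }
        )
    table = pd.DataFrame(rows)
    return OrderSelection(
        table=table,
        aic_order=int(table.loc[table["aic"].idxmin(), "p"]),
        bic_order=int(table.loc[table["bic"].idxmin(), "p"]),
    )


def config_with_seed(config: NMVARConfig, seed: int) -> NMVARConfig:
    return replace(config, seed=int(seed))
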