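"""Linear and non-linear directed connectivity from a trained nMVAR network,
with time-shifted surrogate significance testing.

The fitted predictor f is split into a linear part (its first-order Taylor
expansion at the standardized input mean, i.e. the zero vector) and a
non-linear remainder.  Linear connectivity lC_{i->j} is the mean absolute
Taylor coefficient of channel i (over lags) on output j; non-linear
connectivity NC_{i->j} is the mean absolute deviation of the instantaneous
input-output Jacobian from that Taylor coefficient, averaged over samples
and lags.  For a network with identity activation the Jacobian is constant,
so NC vanishes and lC reduces to the absolute VAR coefficients.

Significance of each directed edge is assessed against a null built from
time-shifted surrogates: every channel is independently circularly shifted
(destroying cross-channel temporal alignment while preserving marginals and
autocorrelation), the network is retrained with identical hyperparameters,
and an edge is significant when its observed strength exceeds the chosen
percentile of its surrogate distribution.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .containers import (
    ConnectivityResult,
    RegressionSampleSet,
    SurrogateNull,
    TimeSeriesMatrix,
    ValidationError,
)
from .model import (
    NMVARConfig,
    NMVARModel,
    TrainingDivergedError,
    fit_ncreann,
)
from .prep import build_regression_samples

logger = logging.getLogger(__name__)


def _act_deriv(model: NMVARModel, pre: np.ndarray) -> np.ndarray:
    if model.activation == "tanh":
        return 1.0 - np.tanh(pre) ** 2
    return np.ones_like(pre)


def taylor_linear_part(model: NMVARModel) -> np.ndarray:
    """Per-lag linear coefficient matrices A (p, M, M), A[tau-1, j, i].

    First-order Taylor expansion of the network at the zero (standardized
    mean) input: the coefficient of lagged channel i at lag tau on output j
    is sum_k outW[j, k] * act'(b1[k]) * hidW[k, (tau-1)*M + i].
    """
    m, p = model.n_channels, model.p
    deriv = _act_deriv(model, model.hidden_biases)  # (H,)
    flat = model.output_weights @ (deriv[:, None] * model.hidden_weights)  # (M, M*p)
    return flat.reshape(m, p, m).transpose(1, 0, 2)  # (p, j, i)


def jacobians(model: NMVARModel, std_inputs: np.ndarray) -> np.ndarray:
    """Instantaneous Jacobians d xhat_j / d x_(i, tau) at each input row.

    Returns an (N, M, M*p) array in the lag-vector column convention.
    """
    pre = std_inputs @ model.hidden_weights.T + model.hidden_biases  # (N, H)
    deriv = _act_deriv(model, pre)  # (N, H)
    return np.einsum("jk,nk,kc->njc", model.output_weights, deriv, model.hidden_weights)


def compute_lc_nc(
    model: NMVARModel,
    samples: RegressionSampleSet,
    channel_labels: list[str] | None = None,
    band: str | None = None,
    condition: str | None = None,
) -> ConnectivityResult:
    """Directed connectivity matrices of one trained model.

    ``samples`` should be the (raw) rows the model was trained on; they are
    mapped into the model's standardized input space before the Jacobians
    are evaluated.
    """
    if samples.n_rows == 0:
        raise ValidationError("empty sample set")
    m, p = model.n_channels, model.p
    a0 = taylor_linear_part(model)                        # (p, j, i)
    lc = np.mean(np.abs(a0), axis=0).T                    # (i, j)
    xstd = model.standardize_inputs(samples.inputs)
    jac = jacobians(model, xstd)                          # (N, j, c)
    a0_flat = a0.transpose(1, 0, 2).reshape(m, m * p)     # (j, c)
    dev = np.abs(jac - a0_flat)                           # (N, j, c)
    nc_cols = dev.mean(axis=0).reshape(m, p, m)           # (j, tau, i)
    nc = nc_cols.mean(axis=1).T                           # (i, j)
    labels = channel_labels or list(model.channel_labels) or [f"ch{i}" for i in range(m)]
    return ConnectivityResult(lc=lc, nc=nc, channel_labels=labels, band=band, condition=condition)


def average_connectivity(results: list[ConnectivityResult]) -> ConnectivityResult:
    """Mean connectivity over fold models (reduces initialization variance)."""
    if not results:
        raise ValidationError("no connectivity results to average")
    lc = np.mean([r.lc for r in results], axis=0)
    nc = np.mean([r.nc for r in results], axis=0)
    first = results[0]
    return ConnectivityResult(
        lc=lc, nc=nc, channel_labels=first.channel_labels,
        band=first.band, condition=first.condition,
    )


def connectivity_from_fit(
    models: list[NMVARModel],
    samples: RegressionSampleSet,
    band: str | None = None,
    condition: str | None = None,
) -> ConnectivityResult:
    """Fold-averaged lC/NC for a list of fold models on common samples."""
    per_fold = [compute_lc_nc(mod, samples, band=band, condition=condition) for mod in models]
    return average_connectivity(per_fold)


def time_shifted_surrogate(
    series: TimeSeriesMatrix, seed: int | np.random.Generator
) -> TimeSeriesMatrix:
    """Independently circular-shift every channel by a random offset.

    Offsets are drawn uniformly from [L/8, 7L/8], so each channel keeps its
    marginal distribution exactly and its autocorrelation up to wraparound
    effects, while cross-channel temporal alignment is destroyed.
    """
    length = series.n_samples
    if length < 16:
        raise ValidationError(f"series of {length} samples too short for surrogate shifting")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = length // 8, (7 * length) // 8
    shifted = np.empty_like(series.values)
    for c in range(series.n_channels):
        offset = int(rng.integers(lo, hi + 1))
        shifted[:, c] = np.roll(series.values[:, c], offset)
    return series.copy_with(values=shifted)


def apply_percentile_mask(
    observed: ConnectivityResult,
    null_lc: np.ndarray,
    null_nc: np.ndarray,
    percentile: float,
    n_requested: int,
    n_dropped: int = 0,
) -> tuple[SurrogateNull, ConnectivityResult]:
    """Threshold observed edges at the per-edge surrogate percentile.

    An edge is significant iff its observed value strictly exceeds the
    ``percentile`` of its null distribution; non-significant edges are set
    to NaN ("missing") in the returned masked result.
    """
    thr_lc = np.percentile(null_lc, percentile, axis=0)
    thr_nc = np.percentile(null_nc, percentile, axis=0)
    sig_lc = observed.lc > thr_lc
    sig_nc = observed.nc > thr_nc
    null = SurrogateNull(
        null_lc=null_lc, null_nc=null_nc, percentile=percentile,
        threshold_lc=thr_lc, threshold_nc=thr_nc,
        significant_lc=sig_lc, significant_nc=sig_nc,
        n_requested=n_requested, n_dropped=n_dropped,
    )
    masked = ConnectivityResult(
        lc=np.abs(np.where(sig_lc, observed.lc, np.nan)),
        nc=np.abs(np.where(sig_nc, observed.nc, np.nan)),
        channel_labels=observed.channel_labels,
        band=observed.band, condition=observed.condition,
    )
    return null, masked


def significance_mask(
    series: TimeSeriesMatrix,
    config: NMVARConfig,
    n_surrogates: int = 100,
    percentile: float = 95.0,
    seed: int | None = None,
    band: str | None = None,
    condition: str | None = None,
) -> tuple[ConnectivityResult, SurrogateNull, ConnectivityResult]:
    """Observed connectivity plus its time-shifted surrogate null.

    Fits the network on ``series``, then for each surrogate: circularly
    shift the channels, rebuild the lag rows, retrain with identical
    hyperparameters (fresh weight initialization under a derived seed) and
    recompute lC/NC.  Returns (observed, null, masked-observed); surrogates
    whose training diverges are dropped and logged, and more than 20%
    dropped aborts the test.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else int(seed))
    shift_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_surrogates)]

    samples = build_regression_samples(series, config.order)
    models, _ = fit_ncreann(samples, config)
    observed = connectivity_from_fit(models, samples, band=band, condition=condition)

    null_lc, null_nc, dropped = [], [], 0
    for s in range(n_surrogates):
        surr = time_shifted_surrogate(series, shift_rng)
        surr_samples = build_regression_samples(surr, config.order)
        try:
            surr_models, _ = fit_ncreann(surr_samples, replace(config, seed=child_seeds[s]))
        except TrainingDivergedError as exc:
            dropped += 1
            logger.warning("surrogate %d dropped: %s", s, exc)
            continue
        res = connectivity_from_fit(surr_models, surr_samples)
        null_lc.append(res.lc)
        null_nc.append(res.nc)
    if dropped > 0.2 * n_surrogates:
        raise TrainingDivergedError(
            f"{dropped}/{n_surrogates} surrogates diverged; null distribution unreliable"
        )
    null, masked = apply_percentile_mask(
        observed, np.asarray(null_lc), np.asarray(null_nc),
        percentile, n_requested=n_surrogates, n_dropped=dropped,
    )
    return observed, null, masked
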