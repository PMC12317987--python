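"""Band-pass filtering, epoch selection, concatenation and lag-vector
construction.

These steps turn raw multichannel source time courses into the regression
samples the network is trained on: filter to the band of interest with a
zero-phase FIR, cut 1000-ms post-stimulus epochs, concatenate the trials of
a condition into one long series (remembering where each trial starts), and
stack p past samples of every channel into lag vectors that never straddle
a trial boundary.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import BANDS, RegressionSampleSet, TimeSeriesMatrix, ValidationError

#: Hamming-window transition-width constant (normalized): tw ~= 3.3 / numtaps.
_HAMMING_TW = 3.3


def design_bandpass_fir(band: str, fs: float) -> np.ndarray:
    """Windowed-sinc FIR taps for a zero-phase band-pass.

    The full transition width is ``min(f_lo/2, (f_hi - f_lo)/2)`` with the
    cutoff centred half a transition below/above the band edges, so that,
    applied forward-backward, the filter holds passband gain within
    [0.9, 1.1] across the band interior while attenuating to <= 0.1 one
    octave outside the edges.  Sharper filters would pass those contracts
    too, but needlessly lengthen the impulse response and worsen the
    collinearity of narrowband lag vectors downstream.
    """
    if band not in BANDS:
        raise ValidationError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    lo, hi = BANDS[band]
    if fs <= 2.0 * hi:
        raise ValidationError(f"fs = {fs} Hz violates Nyquist for band {band}")
    width = min(0.75 * lo, hi - lo)
    numtaps = int(np.ceil(_HAMMING_TW * fs / width))
    numtaps |= 1  # odd length -> symmetric, integer group delay
    taps = signal.firwin(
        numtaps, [lo - width / 2.0, hi + width / 2.0], pass_zero=False, window="hamming", fs=fs
    )
    taps -= taps.mean()  # exact null at DC
    return taps


def bandpass(series: TimeSeriesMatrix, band: str) -> TimeSeriesMatrix:
    """Zero-phase FIR band-pass of every channel (forward-backward filtering)."""
    taps = design_bandpass_fir(band, series.fs)
    min_len = 3 * len(taps)
    if series.n_samples < min_len:
        raise ValidationError(
            f"series of {series.n_samples} samples is shorter than 3x the "
            f"{len(taps)}-tap {band} filter ({min_len} samples required)"
        )
    filtered = signal.filtfilt(taps, [1.0], series.values, axis=0)
    return series.copy_with(values=filtered, band=band)


def select_epochs(
    series: TimeSeriesMatrix,
    onsets: np.ndarray,
    window_ms: tuple[float, float] = (0.0, 1000.0),
) -> list[TimeSeriesMatrix]:
    """Cut post-stimulus epochs, half-open window [start, stop) in ms.

    Each epoch has ``round(fs * (stop - start) / 1000)`` samples; at 256 Hz
    and a [0, 1000) ms window that is 256 samples.
    """
    onsets = np.asarray(onsets, dtype=int)
    start_ms, stop_ms = window_ms
    if stop_ms <= start_ms:
        raise ValidationError("epoch window must have positive duration")
    offset = int(round(series.fs * start_ms / 1000.0))
    n_samp = int(round(series.fs * (stop_ms - start_ms) / 1000.0))
    epochs = []
    for k, onset in enumerate(onsets):
        a = int(onset) + offset
        b = a + n_samp
        if a < 0 or b > series.n_samples:
            raise ValidationError(
                f"trial {k}: onset {onset} with window {window_ms} ms spans "
                f"[{a}, {b}) outside the series of length {series.n_samples}"
            )
        epochs.append(
            TimeSeriesMatrix(
                values=series.values[a:b].copy(),
                fs=series.fs,
                channel_labels=series.channel_labels,
                band=series.band,
            )
        )
    return epochs


def concatenate_trials(epochs: list[TimeSeriesMatrix]) -> TimeSeriesMatrix:
    """Concatenate per-trial epochs into one long series, recording trial starts."""
    if not epochs:
        raise ValidationError("cannot concatenate zero epochs")
    first = epochs[0]
    for k, ep in enumerate(epochs[1:], start=1):
        if ep.channel_labels != first.channel_labels:
            raise ValidationError(f"epoch {k} has a different channel set")
        if ep.fs != first.fs or ep.band != first.band:
            raise ValidationError(f"epoch {k} has mismatched fs or band")
    lengths = [ep.n_samples for ep in epochs]
    boundaries = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(int)
    values = np.vstack([ep.values for ep in epochs])
    return TimeSeriesMatrix(
        values=values,
        fs=first.fs,
        channel_labels=first.channel_labels,
        band=first.band,
        trial_boundaries=boundaries,
    )


def standardize(series: TimeSeriesMatrix) -> tuple[TimeSeriesMatrix, dict[str, np.ndarray]]:
    """Per-channel z-scoring; returns the scaled series and the parameters.

    The returned ``{"mean": ..., "sd": ...}`` allow exact inversion via
    :func:`unstandardize`.
    """
    mean = series.values.mean(axis=0)
    sd = series.values.std(axis=0, ddof=0)
    for i, s in enumerate(sd):
        if s == 0:
            raise ValidationError(
                f"channel {series.channel_labels[i]!r} is constant (zero variance)"
            )
    scaled = (series.values - mean) / sd
    return series.copy_with(values=scaled), {"mean": mean, "sd": sd}


def unstandardize(series: TimeSeriesMatrix, params: dict[str, np.ndarray]) -> TimeSeriesMatrix:
    return series.copy_with(values=series.values * params["sd"] + params["mean"])


def build_regression_samples(series: TimeSeriesMatrix, p: int) -> RegressionSampleSet:
    """Stack lag vectors x_p(n) -> targets x(n), never crossing trial boundaries.

    For each trial segment of length T the admissible targets are samples
    p..T-1, contributing T - p rows; rows whose lag window would span two
    concatenated trials are excluded so concatenation cannot create
    spurious cross-trial dependence.
    """
    if p < 1:
        raise ValidationError("model order p must be >= 1")
    segments = series.trial_segments()
    shortest = min(b - a for a, b in segments)
    if p >= shortest:
        raise ValidationError(
            f"order p = {p} >= shortest trial length {shortest}; no lag rows available"
        )
    x = series.values
    m = series.n_channels
    inputs, targets, src_idx = [], [], []
    for a, b in segments:
        for n in range(a + p, b):
            # [x(n-1) all channels, x(n-2) all channels, ..., x(n-p)]
            inputs.append(x[n - p: n][::-1].reshape(-1))
            targets.append(x[n])
            src_idx.append(n)
    return RegressionSampleSet(
        inputs=np.asarray(inputs),
        targets=np.asarray(targets),
        p=p,
        source_sample_index=np.asarray(src_idx),
        channel_labels=series.channel_labels,
    )
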