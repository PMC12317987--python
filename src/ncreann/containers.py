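"""In-memory containers shared across the pipeline stages.

The central object is :class:`TimeSeriesMatrix`, an (L samples x M channels)
block of source-level activity at a known sampling rate, optionally tagged
with a frequency band and the sample indices at which concatenated trials
start.  Lagged regression samples, voxel volumes and connectivity results
get their own small dataclasses so that every stage has an explicit,
validated contract.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Canonical EEG frequency bands (Hz): theta, alpha, beta.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (15.0, 30.0),
}


class ValidationError(ValueError):
    """Raised when a container or operation input violates its contract."""


@dataclass
class TimeSeriesMatrix:
    """Multichannel source time courses, the x(n) of the nMVAR model.

    Parameters
    ----------
    values : ndarray, shape (L, M)
        One row per sample, one column per channel/region.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Region names, one per column.
    band : str or None
        Frequency band tag (``theta``/``alpha``/``beta``) if the series has
        been band-pass filtered.
    trial_boundaries : ndarray of int
        Sample indices at which concatenated trials start; ``[0]`` for a
        single continuous segment.
    """

    values: np.ndarray
    fs: float
    channel_labels: list[str]
    band: str | None = None
    trial_boundaries: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D (samples x channels) array")
        if self.values.shape[0] == 0:
            raise ValidationError("time series must contain at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("time series contains non-finite values")
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.values.shape[1]} channels"
            )
        if self.band is not None and self.band not in BANDS:
            raise ValidationError(f"unknown band {self.band!r}; expected one of {sorted(BANDS)}")
        if self.trial_boundaries is None:
            self.trial_boundaries = np.array([0], dtype=int)
        self.trial_boundaries = np.asarray(self.trial_boundaries, dtype=int)
        tb = self.trial_boundaries
        if tb.size == 0 or tb[0] != 0:
            raise ValidationError("trial_boundaries must start at sample 0")
        if np.any(np.diff(tb) <= 0) or tb[-1] >= self.n_samples:
            raise ValidationError("trial_boundaries must be strictly increasing and < L")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def trial_segments(self) -> list[tuple[int, int]]:
        """Half-open (start, stop) sample ranges of the concatenated trials."""
        starts = self.trial_boundaries
        stops = np.append(starts[1:], self.n_samples)
        return list(zip(starts.tolist(), stops.tolist()))

    def copy_with(self, **kwargs) -> "TimeSeriesMatrix":
        out = dataclasses.replace(self, **kwargs)
        return out


@dataclass
class RegressionSampleSet:
    """Lagged regression rows: input = x_p(n) (length M*p), target = x(n).

    The lag vector follows the convention
    ``[x_1(n-1), ..., x_M(n-1), x_1(n-2), ..., x_M(n-p)]`` (channel-fastest
    within lag), so column ``(tau-1)*M + i`` holds channel ``i`` at lag
    ``tau``.
    """

    inputs: np.ndarray        # (N, M*p)
    targets: np.ndarray       # (N, M)
    p: int
    source_sample_index: np.ndarray  # (N,) index of the target sample in the series
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        self.source_sample_index = np.asarray(self.source_sample_index, dtype=int)
        n, d = self.inputs.shape
        m = self.targets.shape[1]
        if self.targets.shape[0] != n or self.source_sample_index.shape[0] != n:
            raise ValidationError("inputs, targets and indices must have equal row counts")
        if d != m * self.p:
            raise ValidationError(f"input row length {d} != M*p = {m}*{self.p}")

    @property
    def n_rows(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.targets.shape[1]


@dataclass
class SourceVolume:
    """A regular voxel grid of positive source quantities (power, noise, NAI)."""

    values: np.ndarray              # (nx, ny, nz)
    spacing: float = 5.0            # mm, equal along all axes
    mask: np.ndarray | None = None  # boolean, same shape; e.g. atlas coverage

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValidationError("volume values must be a non-empty 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("volume contains non-finite values")
        if self.spacing <= 0:
            raise ValidationError("voxel spacing must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError("mask shape must match volume shape")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_coordinates_mm(self, indices: np.ndarray) -> np.ndarray:
        """Voxel-centre coordinates (mm) for an (K, 3) array of ijk indices."""
        return np.asarray(indices, dtype=float) * self.spacing


@dataclass
class VoxelClusterSet:
    """DBSCAN output: disjoint voxel clusters plus noise voxels."""

    clusters: list[np.ndarray]   # each (k_i, 3) ijk indices, k_i >= min_pts
    noise: np.ndarray            # (k_noise, 3)
    eps: float
    min_pts: int
    threshold: float | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [int(c.shape[0]) for c in self.clusters]


@dataclass
class ConnectivityResult:
    """M x M directed connectivity: entry (i, j) is the strength of i -> j.

    ``lc`` holds the linear component (mean absolute first-order Taylor
    coefficient across lags), ``nc`` the non-linear component (mean absolute
    deviation of the instantaneous Jacobian from that Taylor coefficient).
    Both are unitless and non-negative.  Diagonal entries quantify
    self-influence and are excluded from group statistics downstream.
    """

    lc: np.ndarray
    nc: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    band: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.lc = np.asarray(self.lc, dtype=float)
        self.nc = np.asarray(self.nc, dtype=float)
        if self.lc.shape != self.nc.shape or self.lc.ndim != 2 or self.lc.shape[0] != self.lc.shape[1]:
            raise ValidationError("lc and nc must be equal square matrices")
        for name, mat in (("lc", self.lc), ("nc", self.nc)):
            # NaN marks a non-significant ("missing") edge in masked results
            if np.any(np.isinf(mat)) or np.any(mat < 0):
                raise ValidationError(f"{name} entries must be non-negative and not infinite")

    @property
    def n_channels(self) -> int:
        return self.lc.shape[0]


@dataclass
class SurrogateNull:
    """Per-edge null distributions and significance masks from time-shifted surrogates."""

    null_lc: np.ndarray          # (S, M, M)
    null_nc: np.ndarray          # (S, M, M)
    percentile: float
    threshold_lc: np.ndarray     # (M, M) per-edge percentile of the null
    threshold_nc: np.ndarray
    significant_lc: np.ndarray   # boolean (M, M): observed > threshold
    significant_nc: np.ndarray
    n_requested: int
    n_dropped: int = 0

    @property
    def n_surrogates(self) -> int:
        return self.null_lc.shape[0]
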