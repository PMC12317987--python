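"""Ground-truth synthetic data: coupled nMVAR time series, source volumes
and prime-probe behavioral tables.

Everything downstream of EEG acquisition is exercised on data produced here,
so each generator carries an explicit specification of its ground truth:
which directed edges exist, where the activity blobs sit, and how strongly
response relation and feature overlap interact behaviorally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BANDS, SourceVolume, TimeSeriesMatrix, ValidationError

NONLINEAR_FORMS = ("quadratic", "tanh", "product")

RESPONSE_LEVELS = ("repetition", "alternation")
OVERLAP_LEVELS = ("no overlap", "full overlap")


@dataclass
class NonlinearTerm:
    """One non-linear generating term added to channel ``target``.

    forms:
      - ``quadratic``: c * x_source(n - lag)**2
      - ``tanh``:      c * tanh(x_source(n - lag))
      - ``product``:   c * x_source(n - lag) * x_target(n - lag)
    """

    target: int
    source: int
    lag: int
    form: str
    coefficient: float

    def __post_init__(self) -> None:
        if self.form not in NONLINEAR_FORMS:
            raise ValidationError(f"unknown nonlinear form {self.form!r}")
        if self.lag < 1:
            raise ValidationError("nonlinear term lag must be >= 1")


@dataclass
class GroundTruthSpec:
    """Generating model for :func:`simulate_nmvar`.

    ``linear_coeffs`` is a list of M x M matrices A_tau for tau = 1..p_true,
    with A_tau[j, i] the linear influence of channel i at lag tau on channel
    j.  The linear part must be stationary (companion-matrix spectral radius
    < 1); non-linear terms are the caller's responsibility to keep bounded.
    """

    n_channels: int
    linear_coeffs: list[np.ndarray]
    nonlinear_terms: list[NonlinearTerm] = field(default_factory=list)
    noise_sd: np.ndarray | float = 1.0
    length: int = 4096
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.n_channels
        if m < 1:
            raise ValidationError("n_channels must be >= 1")
        self.linear_coeffs = [np.asarray(a, dtype=float) for a in self.linear_coeffs]
        for a in self.linear_coeffs:
            if a.shape != (m, m):
                raise ValidationError(f"each linear coefficient matrix must be {m}x{m}")
        self.noise_sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (m,)).copy()
        if np.any(self.noise_sd < 0):
            raise ValidationError("noise_sd must be >= 0")
        if self.length <= 0:
            raise ValidationError("length must be positive")
        p = self.p_true
        for t in self.nonlinear_terms:
            if not (0 <= t.target < m and 0 <= t.source < m):
                raise ValidationError("nonlinear term channel index out of range")
            if t.lag > max(p, 1):
                raise ValidationError("nonlinear term lag exceeds the linear model order")
        if self.burn_in < 10 * max(p, 1):
            raise ValidationError(f"burn_in must be >= 10*p_true = {10 * max(p, 1)}")

    @property
    def p_true(self) -> int:
        return len(self.linear_coeffs)

    def max_lag(self) -> int:
        lags = [self.p_true] + [t.lag for t in self.nonlinear_terms]
        return max(lags) if lags else 1

    def companion_spectral_radius(self) -> float:
        return companion_spectral_radius(self.linear_coeffs)


def companion_spectral_radius(linear_coeffs: list[np.ndarray]) -> float:
    """Spectral radius of the VAR companion matrix of the linear part."""
    if not linear_coeffs:
        return 0.0
    coeffs = [np.asarray(a, dtype=float) for a in linear_coeffs]
    m = coeffs[0].shape[0]
    p = len(coeffs)
    comp = np.zeros((m * p, m * p))
    comp[:m, :] = np.hstack(coeffs)
    if p > 1:
        comp[m:, :-m] = np.eye(m * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def simulate_nmvar(spec: GroundTruthSpec) -> TimeSeriesMatrix:
    """Simulate an nMVAR process x(n) = f(x_p) + sigma(n).

    Each channel is generated by direct recursion as the linear lag sum plus
    the listed non-linear terms plus i.i.d. Gaussian noise; the first
    ``burn_in`` samples are discarded so the returned series is (for the
    stationary linear part) past its transient.
    """
    rho = spec.companion_spectral_radius()
    if rho >= 1.0:
        raise ValidationError(
            f"linear part is non-stationary: companion spectral radius {rho:.4f} >= 1"
        )
    rng = np.random.default_rng(spec.seed)
    m, p = spec.n_channels, spec.p_true
    max_lag = spec.max_lag()
    total = spec.length + spec.burn_in
    x = np.zeros((total + max_lag, m))
    noise = rng.normal(0.0, 1.0, size=(total, m)) * spec.noise_sd
    coeffs = spec.linear_coeffs
    for n in range(max_lag, total + max_lag):
        acc = noise[n - max_lag].copy()
        for tau in range(1, p + 1):
            acc += coeffs[tau - 1] @ x[n - tau]
        for t in spec.nonlinear_terms:
            xs = x[n - t.lag, t.source]
            if t.form == "quadratic":
                val = xs * xs
            elif t.form == "tanh":
                val = math.tanh(xs)
            else:  # product
                val = xs * x[n - t.lag, t.target]
            acc[t.target] += t.coefficient * val
        x[n] = acc
    out = x[max_lag + spec.burn_in:]
    labels = [f"ch{i}" for i in range(m)]
    return TimeSeriesMatrix(values=out, fs=256.0, channel_labels=labels)


def band_resonant_coeffs(band: str, fs: float, pole_radius: float) -> tuple[float, float]:
    """AR(2) coefficients whose spectral peak sits at the centre of ``band``.

    Places a complex-conjugate pole pair at radius r and angle 2*pi*f0/fs,
    giving a1 = 2 r cos(2 pi f0 / fs) and a2 = -r**2.  As r -> 0 the process
    degenerates to white noise.
    """
    if band not in BANDS:
        raise ValidationError(f"unknown band {band!r}")
    if not 0.0 <= pole_radius < 1.0:
        raise ValidationError("pole_radius must lie in [0, 1)")
    lo, hi = BANDS[band]
    if fs <= 2.0 * hi:
        raise ValidationError(f"fs = {fs} Hz violates Nyquist for band {band} ({hi} Hz upper edge)")
    f0 = 0.5 * (lo + hi)
    a1 = 2.0 * pole_radius * math.cos(2.0 * math.pi * f0 / fs)
    a2 = -pole_radius**2
    return a1, a2


def generate_source_volume(
    dims: tuple[int, int, int],
    spacing: float = 5.0,
    blobs: list[tuple[tuple[float, float, float], float, float]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 1.0,
) -> SourceVolume:
    """NAI-like positive volume: baseline + Gaussian blobs + Gaussian noise.

    ``blobs`` is a list of (center_ijk, radius_voxels, amplitude); centres
    must lie inside the grid.  Radius is the Gaussian sigma in voxel units.
    """
    dims = tuple(int(d) for d in dims)
    if min(dims) <= 0:
        raise ValidationError("volume dims must be positive")
    blobs = blobs or []
    grid = np.stack(np.meshgrid(*[np.arange(d) for d in dims], indexing="ij"), axis=-1).astype(float)
    vals = np.full(dims, float(baseline))
    for center, radius, amplitude in blobs:
        c = np.asarray(center, dtype=float)
        if np.any(c < 0) or np.any(c > np.asarray(dims) - 1):
            raise ValidationError(f"blob center {center} lies outside the grid {dims}")
        d2 = np.sum((grid - c) ** 2, axis=-1)
        vals += amplitude * np.exp(-d2 / (2.0 * radius**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=dims)
    return SourceVolume(values=vals, spacing=spacing)


@dataclass
class BehaviorGenSpec:
    """Generating model for prime-probe behavioral tables.

    ``accuracy_means`` and ``rt_means_ms`` map the four design cells
    (response relation x feature overlap) to the cohort-level probability of
    a correct probe response and the mean correct-response RT.  A crossover
    interaction is produced by making accuracy high for repetition/full
    overlap and alternation/no overlap and low in the other two cells.
    ``subject_sd`` is the between-subject spread on the accuracy
    (probability) scale; ``rt_subject_sd_ms`` the spread of subject RT
    intercepts.
    """

    n_subjects: int
    trials_per_condition: int
    accuracy_means: dict[tuple[str, str], float]
    rt_means_ms: dict[tuple[str, str], float]
    rt_sd_ms: float = 80.0
    subject_sd: float = 0.05
    rt_subject_sd_ms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise ValidationError("n_subjects and trials_per_condition must be >= 1")
        cells = [(r, o) for r in RESPONSE_LEVELS for o in OVERLAP_LEVELS]
        for table, name in ((self.accuracy_means, "accuracy_means"), (self.rt_means_ms, "rt_means_ms")):
            missing = [c for c in cells if c not in table]
            if missing:
                raise ValidationError(f"{name} is missing cells: {missing}")
        for c, v in self.accuracy_means.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"accuracy_means{c} = {v} outside [0, 1]")
        if self.rt_sd_ms <= 0:
            raise ValidationError("rt_sd_ms must be > 0")


def generate_behavior(spec: BehaviorGenSpec) -> pd.DataFrame:
    """Simulate a prime-probe behavioral trial table.

    Correctness of the probe response (R2) is Bernoulli around the
    subject-and-cell accuracy; RTs are Gaussian around the subject-and-cell
    mean and drawn only for correct-R2 trials (RT summaries condition on
    correct responses).  Columns: subject, trial, response_relation,
    overlap, correct_r1, correct_r2, rt_ms.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for s in range(spec.n_subjects):
        acc_offset = rng.normal(0.0, spec.subject_sd) if spec.subject_sd > 0 else 0.0
        rt_offset = rng.normal(0.0, spec.rt_subject_sd_ms) if spec.rt_subject_sd_ms > 0 else 0.0
        trial = 0
        for resp in RESPONSE_LEVELS:
            for ov in OVERLAP_LEVELS:
                p_correct = float(np.clip(spec.accuracy_means[(resp, ov)] + acc_offset, 0.0, 1.0))
                mu_rt = spec.rt_means_ms[(resp, ov)] + rt_offset
                correct2 = rng.random(spec.trials_per_condition) < p_correct
                correct1 = rng.random(spec.trials_per_condition) < 0.97
                rts = mu_rt + rng.normal(0.0, spec.rt_sd_ms, size=spec.trials_per_condition)
                for k in range(spec.trials_per_condition):
                    rows.append(
                        {
                            "subject": s,
                            "trial": trial,
                            "response_relation": resp,
                            "overlap": ov,
                            "correct_r1": bool(correct1[k]),
                            "correct_r2": bool(correct2[k]),
                            "rt_ms": float(rts[k]) if correct2[k] else np.nan,
                        }
                    )
                    trial += 1
    return pd.DataFrame(rows)


def crossover_behavior_spec(
    n_subjects: int = 43,
    trials_per_condition: int = 24,
    seed: int = 0,
) -> BehaviorGenSpec:
    """Behavioral spec with the study-like crossover: accuracy high for
    repetition/full-overlap and alternation/no-overlap, low otherwise."""
    return BehaviorGenSpec(
        n_subjects=n_subjects,
        trials_per_condition=trials_per_condition,
        accuracy_means={
            ("repetition", "full overlap"): 0.94,
            ("repetition", "no overlap"): 0.79,
            ("alternation", "no overlap"): 0.96,
            ("alternation", "full overlap"): 0.78,
        },
        rt_means_ms={
            ("repetition", "full overlap"): 480.0,
            ("repetition", "no overlap"): 540.0,
            ("alternation", "no overlap"): 470.0,
            ("alternation", "full overlap"): 555.0,
        },
        rt_sd_ms=80.0,
        subject_sd=0.04,
        rt_subject_sd_ms=40.0,
        seed=seed,
    )
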