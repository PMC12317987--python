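"""Synthetic ground-truth generators: nMVAR simulation, band-resonant
coefficients, source volumes and behavioral tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps_signal

import ncreann as nc
from ncreann.containers import ValidationError
from ncreann.stats import cell_mean_array, rm_anova_2x2, summarize_behavior
from ncreann.synthetic import NonlinearTerm, crossover_behavior_spec

from conftest import simulate_var


class TestSimulateNMVAR:
    def test_zero_coefficients_zero_noise_gives_zero_output(self):
        spec = nc.GroundTruthSpec(
            n_channels=2, linear_coeffs=[np.zeros((2, 2))], noise_sd=0.0,
            length=100, seed=0,
        )
        out = nc.simulate_nmvar(spec)
        assert np.all(out.values == 0.0)

    def test_ar1_stationary_variance_closed_form(self):
        # Var = sigma^2 / (1 - a^2) = 1 / 0.19 = 5.263 for a = 0.9
        spec = nc.GroundTruthSpec(
            n_channels=1, linear_coeffs=[np.array([[0.9]])], noise_sd=1.0,
            length=100_000, seed=7,
        )
        out = nc.simulate_nmvar(spec)
        var = out.values.var()
        assert abs(var - 1.0 / 0.19) / (1.0 / 0.19) < 0.05

    def test_var1_coefficients_recovered_by_least_squares(self):
        a1 = np.array([[0.0, 0.0], [0.5, 0.0]])
        series = simulate_var([a1], length=10_000, seed=3)
        samples = nc.build_regression_samples(series, 1)
        a_hat = nc.ols_var_coefficients(samples)[0]
        assert np.abs(a_hat - a1).max() < 0.05

    def test_fixed_seed_is_bitwise_reproducible(self):
        spec = nc.GroundTruthSpec(
            n_channels=2, linear_coeffs=[np.eye(2) * 0.5], length=500, seed=42,
        )
        a = nc.simulate_nmvar(spec)
        b = nc.simulate_nmvar(spec)
        assert np.array_equal(a.values, b.values)

    def test_linear_part_matches_independent_direct_recursion(self):
        """Same seed, same noise draws: an independent recursion written in
        this test reproduces the generator sample for sample."""
        a1 = np.array([[0.5, 0.1], [0.3, 0.4]])
        spec = nc.GroundTruthSpec(
            n_channels=2, linear_coeffs=[a1], noise_sd=1.0, length=300,
            burn_in=500, seed=9,
        )
        out = nc.simulate_nmvar(spec)
        rng = np.random.default_rng(9)
        total = 300 + 500
        noise = rng.normal(0.0, 1.0, size=(total, 2)) * 1.0
        x = np.zeros((total + 1, 2))
        for n in range(1, total + 1):
            x[n] = a1 @ x[n - 1] + noise[n - 1]
        assert np.array_equal(out.values, x[1 + 500:])

    def test_nonstationary_linear_part_rejected(self):
        spec_kwargs = dict(n_channels=1, linear_coeffs=[np.array([[1.01]])],
                           length=100, seed=0)
        with pytest.raises(ValidationError, match="non-stationary"):
            nc.simulate_nmvar(nc.GroundTruthSpec(**spec_kwargs))

    def test_negative_length_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            nc.GroundTruthSpec(n_channels=1, linear_coeffs=[np.array([[0.5]])],
                               length=-5, seed=0)

    def test_nonlinear_terms_enter_the_recursion(self):
        term = NonlinearTerm(target=1, source=0, lag=1, form="quadratic",
                             coefficient=0.3)
        base = dict(n_channels=2, linear_coeffs=[np.eye(2) * 0.4],
                    noise_sd=1.0, length=2000, seed=5)
        lin = nc.simulate_nmvar(nc.GroundTruthSpec(**base))
        nl = nc.simulate_nmvar(nc.GroundTruthSpec(**base, nonlinear_terms=[term]))
        # channel 0 identical (untouched), channel 1 differs
        assert np.array_equal(lin.values[:, 0], nl.values[:, 0])
        assert not np.allclose(lin.values[:, 1], nl.values[:, 1])


class TestBandResonantCoeffs:
    def test_alpha_spectral_peak_falls_in_band(self):
        a1, a2 = nc.band_resonant_coeffs("alpha", 256.0, 0.95)
        series = simulate_var([np.array([[a1]]), np.array([[a2]])],
                              length=2**14, seed=0)
        freqs, pxx = sps_signal.periodogram(series.values[:, 0], fs=256.0)
        peak = freqs[np.argmax(pxx)]
        assert 8.0 <= peak <= 12.0

    def test_white_noise_limit_as_radius_vanishes(self):
        a1, a2 = nc.band_resonant_coeffs("theta", 256.0, 1e-9)
        assert abs(a1) < 1e-8 and abs(a2) < 1e-8

    def test_lag2_coefficient_is_minus_r_squared(self):
        _, a2 = nc.band_resonant_coeffs("theta", 256.0, 0.95)
        assert a2 == pytest.approx(-0.9025, abs=1e-12)

    def test_unstable_pole_radius_rejected(self):
        with pytest.raises(ValidationError):
            nc.band_resonant_coeffs("alpha", 256.0, 1.0)


def _brute_connected_groups(indices: np.ndarray) -> int:
    """Connected components under 26-neighbourhood adjacency (test oracle)."""
    left = {tuple(v) for v in indices}
    groups = 0
    while left:
        stack = [left.pop()]
        groups += 1
        while stack:
            v = stack.pop()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        nb = (v[0] + dx, v[1] + dy, v[2] + dz)
                        if nb in left:
                            left.remove(nb)
                            stack.append(nb)
    return groups


class TestGenerateSourceVolume:
    def test_single_blob_peak_at_center(self):
        vol = nc.generate_source_volume((10, 10, 10), blobs=[((4, 5, 6), 1.5, 10.0)],
                                        noise_sd=0.0)
        assert np.unravel_index(np.argmax(vol.values), vol.dims) == (4, 5, 6)

    def test_no_blobs_no_noise_constant_baseline(self):
        vol = nc.generate_source_volume((4, 4, 4), blobs=[], noise_sd=0.0, baseline=1.0)
        assert np.all(vol.values == 1.0)

    def test_two_distant_blobs_yield_two_disjoint_top_groups(self):
        vol = nc.generate_source_volume(
            (24, 8, 8),
            blobs=[((4, 4, 4), 1.0, 50.0), ((14, 4, 4), 1.0, 50.0)],
            noise_sd=0.1, seed=1,
        )
        idx, _ = nc.top_percent_threshold(vol, percent=1.0)
        assert _brute_connected_groups(idx) == 2

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValidationError):
            nc.generate_source_volume((0, 5, 5))

    def test_blob_outside_grid_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            nc.generate_source_volume((5, 5, 5), blobs=[((9, 0, 0), 1.0, 1.0)])


class TestGenerateBehavior:
    def test_degenerate_noise_reproduces_cell_means_exactly(self):
        spec = nc.BehaviorGenSpec(
            n_subjects=4, trials_per_condition=10,
            accuracy_means={c: 1.0 for c in _cells()},
            rt_means_ms={c: 500.0 + 10 * k for k, c in enumerate(_cells())},
            rt_sd_ms=1e-12, subject_sd=0.0, seed=0,
        )
        table = nc.generate_behavior(spec)
        assert table["correct_r2"].all()
        summary = summarize_behavior(table)
        for k, (resp, ov) in enumerate(_cells()):
            cell = summary[(summary.response_relation == resp) & (summary.overlap == ov)]
            assert np.allclose(cell["mean_rt_ms"], 500.0 + 10 * k, atol=1e-6)

    def test_crossover_spec_detects_interaction_with_high_power(self):
        """Crossover accuracy means near the observed behavioral effect:
        the 2x2 interaction is detected in >= 90% of 100 cohorts."""
        detected = 0
        for cohort in range(100):
            table = nc.generate_behavior(crossover_behavior_spec(seed=1000 + cohort))
            arr = cell_mean_array(summarize_behavior(table))
            if rm_anova_2x2(arr)["interaction"].p < 0.05:
                detected += 1
        assert detected >= 90

    def test_empty_cells_rejected(self):
        with pytest.raises(ValidationError, match="missing cells"):
            nc.BehaviorGenSpec(
                n_subjects=2, trials_per_condition=5,
                accuracy_means={("repetition", "no overlap"): 0.9},
                rt_means_ms={c: 500.0 for c in _cells()},
            )

    def test_rt_missing_only_on_incorrect_trials(self):
        spec = crossover_behavior_spec(n_subjects=3, seed=2)
        table = nc.generate_behavior(spec)
        assert table.loc[~table.correct_r2, "rt_ms"].isna().all()
        assert table.loc[table.correct_r2, "rt_ms"].notna().all()


def _cells():
    return [(r, o) for r in ("repetition", "alternation")
            for o in ("no overlap", "full overlap")]
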