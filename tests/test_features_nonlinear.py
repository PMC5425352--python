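"""Katz fractal dimension, Renyi entropy, wavelet entropies."""

import math

import numpy as np
import pytest

from ecgcreativity.features_nonlinear import (
    coefficient_entropies,
    katz_fd,
    katz_measures,
    renyi_entropy,
    wavelet_decompose,
    wavelet_entropies,
)


def katz_oracle(x, dt=1.0):
    """Independent direct evaluation of the Katz curve formulas."""
    pts = [(i * dt, float(v)) for i, v in enumerate(x)]
    L = sum(math.dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1))
    d = max(math.dist(pts[0], p) for p in pts)
    a = L / (len(pts) - 1)
    n = L / a
    return math.log10(n) / (math.log10(n) + math.log10(d / L))


def shannon_oracle(p):
    return -sum(pi * math.log(pi) for pi in p if pi > 0)


class TestKatz:
    @pytest.mark.parametrize("slope", [0.0, 1.0, -3.5])
    def test_straight_line_is_exactly_one(self, slope):
        x = slope * np.arange(50, dtype=float)
        assert katz_fd(x) == 1.0

    def test_matches_independent_oracle_on_random_waveforms(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 200))
            x = rng.standard_normal(n) * rng.uniform(0.1, 10)
            assert katz_fd(x) == pytest.approx(katz_oracle(x), abs=1e-12)

    def test_sine_matches_oracle(self):
        x = np.sin(2 * np.pi * np.arange(1000) / 100.0)
        assert katz_fd(x) == pytest.approx(katz_oracle(x), abs=1e-12)

    def test_square_alternation_exceeds_one(self):
        x = np.tile([0.0, 1.0], 32)
        D = katz_fd(x)
        assert D > 1.0
        assert D == pytest.approx(katz_oracle(x), abs=1e-12)

    def test_offset_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(128)
        assert katz_fd(x + 17.3) == pytest.approx(katz_fd(x), abs=1e-12)

    def test_time_reversal_near_invariance(self):
        # the diameter is measured from the first point, so reversal is only
        # approximately neutral; it must not change D materially
        rng = np.random.default_rng(6)
        x = np.cumsum(rng.standard_normal(256))
        assert katz_fd(x[::-1]) == pytest.approx(katz_fd(x), rel=0.01)

    def test_measures_consistency(self):
        x = np.array([0.0, 2.0, 1.0, 3.0])
        m = katz_measures(x)
        assert m.L >= m.d > 0
        assert m.n_steps == 3
        assert m.a == pytest.approx(m.L / 3)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            katz_fd(np.array([0.0, 1.0]))


class TestRenyi:
    @pytest.mark.parametrize("alpha", [0.5, 2.0, 3.0])
    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_uniform_k_bins_gives_log_k(self, alpha, k):
        # k distinct values with equal counts, binned into exactly k bins
        x = np.repeat(np.arange(k, dtype=float), 20)
        assert renyi_entropy(x, alpha=alpha, n_bins=k) == pytest.approx(
            math.log(k), abs=1e-12)

    def test_constant_signal_is_zero(self):
        assert renyi_entropy(np.full(100, 3.3)) == 0.0

    def test_alpha_near_one_converges_to_shannon(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        counts, _ = np.histogram(x, bins=30)
        p = counts[counts > 0] / x.size
        sh = shannon_oracle(p)
        lo = renyi_entropy(x, alpha=1 - 1e-4, n_bins=30)
        hi = renyi_entropy(x, alpha=1 + 1e-4, n_bins=30)
        assert min(lo, hi) <= sh <= max(lo, hi)
        assert lo == pytest.approx(sh, abs=1e-3)
        assert hi == pytest.approx(sh, abs=1e-3)

    def test_monotone_nonincreasing_in_alpha(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        vals = [renyi_entropy(x, alpha=a, n_bins=50) for a in (0.5, 2.0, 3.0)]
        assert vals[0] >= vals[1] >= vals[2] >= 0.0

    @pytest.mark.parametrize("alpha", [0.0, -1.0, 1.0])
    def test_invalid_alpha_errors(self, alpha):
        with pytest.raises(ValueError):
            renyi_entropy(np.arange(10.0), alpha=alpha)


class TestWaveletEntropies:
    def test_zero_signal_conventions(self):
        we = wavelet_entropies(np.zeros(256))
        assert we.shannon == 0.0 and we.log_energy == 0.0 and we.norm == 0.0

    def test_single_unit_coefficient(self):
        we = coefficient_entropies(np.array([1.0, 0.0, 0.0, 0.0]), p=1.0)
        assert we.shannon == 0.0
        assert we.norm == 1.0

    def test_frozen_pair_values(self):
        we = coefficient_entropies(np.array([0.5, 0.5]), p=1.1)
        assert we.shannon == pytest.approx(0.6931472, abs=1e-6)
        assert we.log_energy == pytest.approx(-2.7725887, abs=1e-6)
        assert we.norm == pytest.approx(0.9330330, abs=1e-6)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(1024)
        s = wavelet_decompose(x)
        we = wavelet_entropies(x)
        shannon = -sum(v * v * math.log(v * v) for v in s if v != 0.0)
        log_energy = sum(math.log(v * v) for v in s if v != 0.0)
        norm = sum(abs(v) ** 1.1 for v in s)
        assert we.shannon == pytest.approx(shannon, abs=1e-12 * max(1, abs(shannon)))
        assert we.log_energy == pytest.approx(log_energy, rel=1e-12)
        assert we.norm == pytest.approx(norm, rel=1e-12)

    def test_energy_conservation(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(4096)
        s = wavelet_decompose(x)
        assert np.sum(s**2) == pytest.approx(np.sum(x**2), rel=1e-8)

    def test_signal_too_short_for_level_errors(self):
        with pytest.raises(ValueError, match="too short"):
            wavelet_entropies(np.zeros(16), level=5)
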