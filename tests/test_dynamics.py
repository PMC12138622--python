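"""Entropy, embedding, tau selection and linear comparison operations."""

import numpy as np
import pytest

from kpbiofilm import dynamics as dyn
from kpbiofilm.errors import DataError, EstimationError, ParameterError


def make_trace(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return dyn.SignalTrace(time=np.arange(values.size) * dt, potential=values)


class TestShannonEntropy:
    def test_constant_trace_is_zero_bits(self):
        ent = dyn.shannon_entropy(make_trace(np.full(100, 3.7)))
        assert ent.H == 0.0
        assert ent.occupancy.sum() == pytest.approx(1.0, abs=1e-12)

    def test_eight_equal_bins_give_three_bits(self):
        ent = dyn.shannon_entropy(make_trace(np.tile(np.arange(8.0), 5)))
        assert ent.H == 3.0

    def test_two_levels_give_one_bit(self):
        ent = dyn.shannon_entropy(make_trace([0.0] * 6 + [1.0] * 6))
        assert ent.H == 1.0

    @pytest.mark.parametrize("scale,offset", [(2.5, 0.0), (1.0, -40.0), (0.02, 7.0)])
    def test_affine_invariance_under_observed_range(self, scale, offset):
        rng = np.random.default_rng(11)
        v = rng.normal(size=400)
        h0 = dyn.shannon_entropy(make_trace(v)).H
        h1 = dyn.shannon_entropy(make_trace(scale * v + offset)).H
        assert h1 == pytest.approx(h0, abs=1e-12)

    def test_bounded_by_log2_bins_and_zero_iff_single_bin(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v = rng.normal(size=200)
            ent = dyn.shannon_entropy(make_trace(v))
            assert 0.0 <= ent.H <= np.log2(ent.n_bins) + 1e-12
            assert (ent.H == 0.0) == (np.count_nonzero(ent.occupancy) == 1)

    def test_fixed_range_confined_signal_is_zero_bits(self):
        # a non-constant trace confined inside one bin of a wide absolute range
        v = 0.1 + 0.01 * np.sin(np.linspace(0, 6, 200))
        ent = dyn.shannon_entropy(make_trace(v), range_mode="fixed", fixed_range=(-5, 5))
        assert ent.H == 0.0

    def test_empty_and_bad_inputs(self):
        with pytest.raises(DataError):
            make_trace([])
        with pytest.raises(ParameterError):
            dyn.shannon_entropy(make_trace(np.arange(10.0)), n_bins=1)


class TestDelayEmbed:
    def test_point_count(self):
        emb = dyn.delay_embed(make_trace(np.arange(10.0)), dyn.EmbeddingConfig(tau=3, m=2))
        assert emb.shape == (7, 2)

    @pytest.mark.parametrize("m,tau", [(2, 1), (3, 2), (4, 5)])
    def test_point_count_formula(self, m, tau):
        n = 100
        emb = dyn.delay_embed(make_trace(np.arange(float(n))), dyn.EmbeddingConfig(tau=tau, m=m))
        assert emb.shape == (n - (m - 1) * tau, m)

    def test_quarter_period_sinusoid_embeds_to_circle(self):
        period = 100
        t = np.arange(3000.0)
        amp = 2.3
        trace = make_trace(amp * np.sin(2 * np.pi * t / period))
        emb = dyn.delay_embed(trace, dyn.EmbeddingConfig(tau=period // 4, m=2))
        radii = np.linalg.norm(emb, axis=1)
        assert np.max(np.abs(radii - amp)) < 1e-6 * amp

    def test_m_one_rejected(self):
        with pytest.raises(ParameterError):
            dyn.EmbeddingConfig(tau=1, m=1)

    def test_too_short_trace(self):
        with pytest.raises(DataError):
            dyn.delay_embed(make_trace(np.arange(5.0)), dyn.EmbeddingConfig(tau=3, m=3))


class TestEstimateTau:
    def test_sinusoid_gives_quarter_period(self):
        period = 80
        t = np.arange(2000.0)
        tau = dyn.estimate_tau(make_trace(np.sin(2 * np.pi * t / period)))
        assert abs(tau - period // 4) <= 1

    def test_white_noise_crosses_immediately(self):
        taus = [
            dyn.estimate_tau(make_trace(np.random.default_rng(s).normal(size=500)))
            for s in range(50)
        ]
        assert min(taus) == 1
        assert np.mean(taus) < 4  # geometric-ish decay of first non-positive lag

    def test_constant_trace_falls_back(self):
        tau = dyn.estimate_tau(make_trace(np.full(200, 1.0)))
        assert tau == 200 // 20


class TestCrossCorrelation:
    def test_self_correlation_is_one_at_zero_lag(self):
        a = make_trace(np.random.default_rng(0).normal(size=300))
        cc = dyn.cross_correlation(a, a, max_lag=10)
        assert cc[10] == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip(self):
        v = np.random.default_rng(1).normal(size=300)
        cc = dyn.cross_correlation(make_trace(v), make_trace(-v), max_lag=5)
        assert cc[5] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_noise_is_small_everywhere(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            a = make_trace(rng.normal(size=10_000))
            b = make_trace(rng.normal(size=10_000))
            cc = dyn.cross_correlation(a, b, max_lag=50)
            assert np.max(np.abs(cc)) < 0.05

    def test_zero_variance_yields_nan_markers(self):
        a = make_trace(np.full(100, 2.0))
        b = make_trace(np.random.default_rng(0).normal(size=100))
        assert np.all(np.isnan(dyn.cross_correlation(a, b, max_lag=3)))


class TestPercentileExtremes:
    def test_quantile_oracle_on_integer_sequence(self):
        lo, hi, spread = dyn.percentile_extremes(make_trace(np.arange(1.0, 101.0)))
        assert spread == pytest.approx(49.5)
        assert lo == pytest.approx(25.75)
        assert hi == pytest.approx(75.25)

    def test_constant_spread_zero_and_translation_invariance(self):
        assert dyn.percentile_extremes(make_trace(np.full(10, 4.0)))[2] == 0.0
        v = np.random.default_rng(2).normal(size=50)
        s0 = dyn.percentile_extremes(make_trace(v))[2]
        s1 = dyn.percentile_extremes(make_trace(v + 123.4))[2]
        assert s1 == pytest.approx(s0, abs=1e-9)


class TestEstimatorContracts:
    def test_constant_trace_d2_is_error(self):
        with pytest.raises(EstimationError):
            dyn.correlation_dimension(
                make_trace(np.full(600, 1.0)), dyn.EmbeddingConfig(tau=1, m=2)
            )

    def test_constant_trace_le_is_error(self):
        with pytest.raises(EstimationError):
            dyn.largest_lyapunov(
                make_trace(np.full(600, 1.0)), dyn.EmbeddingConfig(tau=1, m=2)
            )

    def test_estimators_are_deterministic(self):
        t = np.arange(1500.0)
        v = np.sin(2 * np.pi * t / 101.3) + 0.1 * np.sin(2 * np.pi * t / 17.0)
        cfg = dyn.EmbeddingConfig(tau=25, m=2)
        le = [dyn.largest_lyapunov(make_trace(v), cfg) for _ in range(2)]
        d2 = [dyn.correlation_dimension(make_trace(v), cfg) for _ in range(2)]
        assert le[0] == le[1]
        assert d2[0] == d2[1]
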