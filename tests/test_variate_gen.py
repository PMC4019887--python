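"""Geometric/exponential variate generation and the software baseline."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from probfab.circuit_rng import BitStream
from probfab.variate_gen import (
    LCG_MODULUS,
    ChaosBackend,
    ExponentialSampler,
    HardwareBackend,
    LcgState,
    PriorityEncoder,
    SoftwareBackend,
    TransferFunction,
    first_success_index,
    geometric_pmf,
    lcg_uniform,
    make_backend,
    sample_arbitrary,
    sample_exponential_hw,
    sample_exponential_sw,
    sample_geometric_encoder,
)


class TestGeometricPmf:
    def test_first_trial_success(self):
        assert geometric_pmf(1, 0.2) == pytest.approx(0.2)

    def test_three_bit_enumeration(self):
        # oracle: enumerate all eight equally likely 3-bit patterns and
        # count those whose first success lands on trial 3
        patterns = list(itertools.product([0, 1], repeat=3))
        hits = sum(1 for p in patterns if p[0] == 0 and p[1] == 0 and p[2] == 1)
        assert geometric_pmf(3, 0.5) == pytest.approx(hits / len(patterns))

    @pytest.mark.parametrize("p", [0.05, 0.3, 0.9, 1.0])
    def test_normalization_via_tail(self, p):
        k_max = 2000
        head = sum(geometric_pmf(k, p) for k in range(1, k_max + 1))
        tail = (1 - p) ** k_max
        assert head + tail == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("k, p", [(0, 0.5), (1, 0.0), (1, 1.1), (-2, 0.5)])
    def test_domain_errors(self, k, p):
        with pytest.raises(ValueError):
            geometric_pmf(k, p)


class TestPriorityEncoder:
    def test_reads_first_asserted_input(self):
        enc = PriorityEncoder(width=8)
        word = np.array([0, 0, 1, 0, 1, 0, 0, 0])
        assert first_success_index(word, enc) == 3

    def test_all_zero_word_overflows(self):
        enc = PriorityEncoder(width=32)
        assert first_success_index(np.zeros(32, dtype=np.uint8), enc) is None

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            first_success_index(np.zeros(8, dtype=np.uint8), PriorityEncoder(width=32))

    def test_accepts_bitstream_input(self):
        stream = BitStream(bits=np.array([0, 1, 0, 0], dtype=np.uint8))
        assert first_success_index(stream, PriorityEncoder(width=4)) == 2

    def test_empirical_pmf_at_half(self, rng):
        k = sample_geometric_encoder(0.5, PriorityEncoder(), rng, size=100_000)
        assert np.mean(k == 3) == pytest.approx(0.125, abs=0.004)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_chained_index_is_exactly_geometric(self, rng, p):
        # chain mode: the accumulated index follows the geometric law for
        # any encoder width, by memorylessness across read-out banks
        n = 100_000
        k = sample_geometric_encoder(p, PriorityEncoder(width=7), rng, size=n)
        k_cap = int(np.quantile(k, 0.9999)) + 1
        obs = np.bincount(np.minimum(k, k_cap), minlength=k_cap + 1)[1:]
        pmf = np.array([geometric_pmf(i, p) for i in range(1, k_cap)] + [(1 - p) ** (k_cap - 1)])
        res = stats.chisquare(obs, pmf * n)
        assert res.pvalue > 0.01

    def test_saturate_mode_caps_and_reports_bias(self, rng):
        enc = PriorityEncoder(width=8, overflow_policy="saturate")
        k = sample_geometric_encoder(0.05, enc, rng, size=20_000)
        assert k.max() <= 8
        assert enc.saturate_bias(0.05) == pytest.approx(0.95**8)
        sampler = ExponentialSampler(rate=1.0, quantum=-math.log(0.95), encoder=enc)
        assert sampler.saturate_bias == pytest.approx(0.95**8)


class TestExponentialSamplerHw:
    def test_degenerate_large_quantum(self):
        # p -> 1: every first trial succeeds, so every draw equals one quantum
        sampler = ExponentialSampler(rate=1.0, quantum=50.0)
        taus = sample_exponential_hw(sampler, seed=0, size=100)
        assert np.allclose(taus, 50.0)

    def test_mean_matches_geometric_formula(self, rng):
        sampler = ExponentialSampler(rate=2.0, quantum=0.02)
        taus = sampler.sample(rng, size=100_000)
        assert taus.mean() == pytest.approx(sampler.quantum / sampler.p, rel=0.01)

    def test_quantized_law_within_ks_bound_of_exponential(self):
        # the quantized CDF agrees with Exponential(rate) at every grid
        # point; the analytic sup distance is the first-cell mass p
        sampler = ExponentialSampler(rate=1.0, quantum=0.01)
        assert sampler.ks_bound() == pytest.approx(1 - math.exp(-0.01))
        assert sampler.ks_bound() < 0.01
        k = np.arange(1, 2000)
        grid_cdf = 1 - (1 - sampler.p) ** k
        assert np.allclose(grid_cdf, stats.expon.cdf(k * 0.01), atol=1e-12)

    def test_dequantized_sample_ks_converges(self):
        sampler = ExponentialSampler(rate=1.0, quantum=0.01, mode="dequantized")
        taus = sample_exponential_hw(sampler, seed=11, size=100_000)
        assert stats.kstest(taus, stats.expon.cdf).statistic < 0.01

    def test_invariants(self):
        with pytest.raises(ValueError):
            ExponentialSampler(rate=0.0, quantum=0.1)
        with pytest.raises(ValueError):
            ExponentialSampler(rate=1.0, quantum=0.0)
        with pytest.raises(ValueError):
            ExponentialSampler(rate=1.0, quantum=0.1, mode="weird")


class TestLcg:
    def test_minimal_standard_first_step(self):
        state, u = lcg_uniform(LcgState(1))
        assert state.state == 16807
        assert u == pytest.approx(16807 / LCG_MODULUS)

    def test_no_repeat_in_prefix(self):
        seen = set()
        state = LcgState(1)
        for _ in range(100_000):
            state, _ = lcg_uniform(state)
            assert state.state not in seen
            seen.add(state.state)

    def test_outputs_strictly_inside_unit_interval(self):
        state = LcgState(987654321)
        for _ in range(10_000):
            state, u = lcg_uniform(state)
            assert 0.0 < u < 1.0

    def test_zero_state_rejected(self):
        with pytest.raises(ValueError):
            LcgState(0)


class TestExponentialSw:
    def test_matches_inverse_transform_identity(self):
        state0 = LcgState(777)
        _, u = lcg_uniform(state0)
        _, e = sample_exponential_sw(3.0, state0)
        assert e == pytest.approx(-math.log(u) / 3.0)

    def test_log_identity_at_euler_uniform(self):
        # E = -ln(U)/rate gives exactly 1 when U = e^-1 at rate 1
        assert -math.log(math.exp(-1.0)) / 1.0 == pytest.approx(1.0)

    def test_sample_mean_at_rate_two(self):
        state = LcgState(424242)
        total = 0.0
        n = 100_000
        for _ in range(n):
            state, e = sample_exponential_sw(2.0, state)
            total += e
        assert total / n == pytest.approx(0.5, rel=0.01)

    def test_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            sample_exponential_sw(0.0, LcgState(1))


class TestTransferFunction:
    def test_binary_fraction_identity(self):
        tf = TransferFunction(inverse_cdf=lambda u: u, bit_depth=8)
        bits = np.array([1, 0, 0, 0, 0, 0, 0, 0], dtype=np.uint8)
        assert sample_arbitrary(tf, bits) == pytest.approx(0.5)

    def test_exponential_inverse_cdf(self, rng):
        tf = TransferFunction(inverse_cdf=lambda u: -math.log1p(-u), bit_depth=16)
        bits = rng.integers(0, 2, size=16).astype(np.uint8)
        u = sum(b * 0.5 ** (i + 1) for i, b in enumerate(bits))
        assert sample_arbitrary(tf, bits) == pytest.approx(-math.log(1 - u), abs=1e-12)

    def test_mixture_target_by_ks(self, rng):
        # two-component uniform mixture with a closed-form quantile function
        def inv(u):
            return u / 0.3 if u < 0.3 else 2.0 + (u - 0.3) / 0.7

        def cdf(x):
            x = np.asarray(x, dtype=float)
            return np.where(x < 1.0, 0.3 * np.clip(x, 0, 1), np.where(x < 2.0, 0.3, 0.3 + 0.7 * np.clip(x - 2.0, 0, 1)))

        tf = TransferFunction(inverse_cdf=inv, bit_depth=16)
        words = rng.integers(0, 2, size=(100_000, 16)).astype(np.uint8)
        draws = np.array([sample_arbitrary(tf, w) for w in words])
        assert stats.kstest(draws, cdf).statistic < 0.01

    def test_bit_depth_mismatch(self):
        tf = TransferFunction(inverse_cdf=lambda u: u, bit_depth=4)
        with pytest.raises(ValueError):
            sample_arbitrary(tf, np.zeros(5, dtype=np.uint8))


class TestBackends:
    def test_factory_dispatch(self):
        assert isinstance(make_backend("software", 1), SoftwareBackend)
        assert isinstance(make_backend("hardware", 1), HardwareBackend)
        assert isinstance(make_backend("chaos", 1), ChaosBackend)
        with pytest.raises(ValueError):
            make_backend("quantum", 1)

    def test_hardware_backend_shares_one_quantum(self, rng):
        backend = HardwareBackend(seed=3, quantum_factor=0.5)
        taus = backend.sample_times(np.array([2.0, 4.0]))
        # quantum = 0.5 / max(rate) = 0.125; every tau is a multiple of it
        assert np.allclose(np.mod(taus, 0.125), 0.0)

    def test_hardware_backend_counts_overflows(self):
        backend = HardwareBackend(seed=5, quantum_factor=0.001)
        for _ in range(50):
            backend.sample_times(np.array([1.0]))
        assert backend.overflow_count > 0  # mean index ~1000 >> width 32

    @pytest.mark.parametrize("name", ["software", "hardware", "chaos"])
    def test_backend_sample_means(self, name):
        backend = make_backend(name, 99)
        taus = backend.sample_times(np.full(20_000, 2.0))
        assert taus.mean() == pytest.approx(0.5, rel=0.05)
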