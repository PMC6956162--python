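import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

import dicmflex as dx
from dicmflex.codes import ADMISSIBLE_CODES, N_CODES, Estimator
from dicmflex.coupling import (
    DsteConfig,
    aec,
    candidate_strength,
    dpli,
    dpli_strength,
    dste,
    embed,
    estimate_all,
    iplv,
    neural_gas_codebook,
    pac,
    precompute,
    symbolic_te,
    symbolize,
)
from dicmflex.preprocessing import filterbank, make_windows
from dicmflex.signal_io import Recording
from dicmflex.synthetic_data import CouplingEntry, gen_band_noise, gen_recording


class TestAnalyticLimits:
    """Closed-form values of the phase/envelope estimators."""

    def test_iplv_constant_lags(self, rng):
        base = rng.uniform(-np.pi, np.pi, 400)
        assert iplv(base + np.pi / 2, base) == pytest.approx(1.0, abs=1e-9)
        assert iplv(base, base) == pytest.approx(0.0, abs=1e-9)
        assert iplv(base + np.pi / 6, base) == pytest.approx(0.5, abs=1e-9)

    def test_dpli_lead_lag_and_tie(self, rng):
        base = rng.uniform(-1.0, 1.0, 400)
        assert dpli(base + 0.3, base) == pytest.approx(1.0, abs=1e-9)
        assert dpli(base - 0.3, base) == pytest.approx(0.0, abs=1e-9)
        assert dpli(base, base) == pytest.approx(0.5, abs=1e-9)
        assert dpli_strength(0.5) == 0.0

    def test_aec_identical_and_reversed(self, rng):
        env = rng.uniform(0.5, 2.0, 340)
        assert aec(env, env) == pytest.approx(1.0, abs=1e-9)
        assert aec(env, 10.0 - env) == pytest.approx(-1.0, abs=1e-9)

    def test_aec_zero_variance_flagged(self):
        assert np.isnan(aec(np.ones(100), np.arange(100.0)))

    def test_too_short_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            iplv(np.zeros(4), np.zeros(4))
        with pytest.raises(ValueError):
            dpli(np.zeros(4), np.zeros(4))

    def test_aec_null_level(self, rng):
        """Independent 340-sample envelopes rarely correlate past 0.2."""
        hits = 0
        reps = 1000
        for _ in range(reps):
            a = rng.uniform(0.0, 1.0, 340)
            b = rng.uniform(0.0, 1.0, 340)
            hits += abs(aec(a, b)) < 0.2
        assert hits / reps >= 0.95


class TestEstimatorInvariances:
    @given(st.floats(-np.pi, np.pi))
    @settings(max_examples=25, deadline=None)
    def test_iplv_and_dpli_invariant_to_common_phase_offset(self, offset):
        rng = np.random.default_rng(7)
        pa = rng.uniform(-np.pi, np.pi, 256)
        pb = rng.uniform(-np.pi, np.pi, 256)
        assert iplv(pa + offset, pb + offset) == pytest.approx(
            iplv(pa, pb), abs=1e-9
        )
        # dpli compares wrapped differences, which the offset cancels from
        assert dpli(pa + offset, pb + offset) == pytest.approx(
            dpli(pa, pb), abs=1e-9
        )

    @given(st.floats(0.1, 50.0), st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_aec_invariant_to_positive_affine_rescaling(self, scale, shift):
        rng = np.random.default_rng(8)
        a = rng.uniform(0.5, 2.0, 128)
        b = rng.uniform(0.5, 2.0, 128)
        assert aec(scale * a + shift, b) == pytest.approx(aec(a, b), abs=1e-9)


class TestPac:
    def test_cross_band_pair_count(self):
        assert len(ADMISSIBLE_CODES[Estimator.PAC]) == 28

    def test_depth_one_synthesis_recovers_strong_coupling(self):
        entry = CouplingEntry((0, 1), "pac", "theta", "gamma", strength=1.0)
        rec = gen_recording(2, 170.0, 8.0, [entry], seed=5)
        banded = filterbank(rec)
        strength = pac(banded.phase[1, 0, 340:-340],
                       banded.envelope[7, 1, 340:-340], 1, rec.fs)
        assert strength > 0.8

    def test_pac_strictly_increasing_in_depth(self):
        """Mean estimated PAC rises monotonically with modulation depth."""
        depths = (0.0, 0.25, 0.5, 0.75, 1.0)
        means = []
        for depth in depths:
            vals = []
            for rep in range(20):
                entry = CouplingEntry((0, 1), "pac", "theta", "gamma",
                                      strength=depth)
                rec = gen_recording(2, 170.0, 4.0, [entry], seed=600 + rep)
                banded = filterbank(rec)
                vals.append(pac(banded.phase[1, 0, 170:-170],
                                banded.envelope[7, 1, 170:-170], 1, rec.fs))
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestNeuralGas:
    def test_well_separated_clusters_recovered(self, rng):
        centers = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        X = np.concatenate([rng.normal(c, 0.1, (60, 2)) for c in centers])
        W = neural_gas_codebook(X, 3, seed=2)
        for c in centers:
            assert np.min(np.linalg.norm(W - c, axis=1)) < 0.1  # within 1 sd

    def test_single_prototype_is_global_mean(self, rng):
        X = rng.normal(size=(50, 3))
        np.testing.assert_allclose(neural_gas_codebook(X, 1)[0], X.mean(0),
                                   atol=1e-12)

    def test_deterministic_under_fixed_seed(self, rng):
        X = rng.normal(size=(100, 3))
        np.testing.assert_array_equal(neural_gas_codebook(X, 4, seed=9),
                                      neural_gas_codebook(X, 4, seed=9))

    def test_too_few_distinct_vectors_rejected(self):
        X = np.tile([[1.0, 2.0]], (10, 1))
        with pytest.raises(ValueError, match="distinct"):
            neural_gas_codebook(X, 3)


class TestDste:
    def _symbol_pair(self, seed, delay=3, noise=0.1, n=1200, k=8):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, k, n)
        b = np.roll(a, delay)
        flip = rng.random(n) < noise
        b[flip] = rng.integers(0, k, flip.sum())
        return a, b

    def test_shifted_noisy_copy_recovers_direction_and_delay(self):
        a, b = self._symbol_pair(seed=3)
        res = dste(a, b, 8, range(1, 6))
        assert res.direction == 1
        assert res.delay == 3
        assert res.strength > 0.5

    def test_direction_recovery_rate(self):
        """Direction recovered in >= 90% of noisy delayed-copy constructions."""
        hits = 0
        for rep in range(30):
            a, b = self._symbol_pair(seed=100 + rep,
                                     delay=1 + rep % 5)
            hits += dste(a, b, 8, range(1, 6)).direction == 1
        assert hits / 30 >= 0.9

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(4)
        low = 0
        for rep in range(20):
            a = rng.integers(0, 8, 1200)
            b = rng.integers(0, 8, 1200)
            low += dste(a, b, 8, range(1, 6)).strength < 0.25
        assert low / 20 >= 0.95

    def test_identical_series_symmetric(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 8, 800)
        res = dste(a, a.copy(), 8, range(1, 6))
        assert abs(res.te_ab - res.te_ba) < 1e-9

    def test_constant_series_degenerate(self):
        res = dste(np.zeros(500, dtype=int), np.ones(500, dtype=int), 8)
        assert res.degenerate
        assert res.strength == 0.0

    def test_signal_level_direction_and_delay(self):
        """Band-noise source driving a delayed copy: direction and lag found."""
        rng = np.random.default_rng(6)
        x = gen_band_noise("gamma", 170.0, 12.0, rng)
        y = np.roll(x, 3) + 0.3 * gen_band_noise("gamma", 170.0, 12.0, rng)
        cb = neural_gas_codebook(embed(x), 8, seed=1)
        res = dste(symbolize(x, cb), symbolize(y, cb), 8, range(1, 11))
        assert res.direction == 1
        assert res.delay == 3

    def test_te_normalization_bounds(self, rng):
        a = rng.integers(0, 4, 600)
        b = rng.integers(0, 4, 600)
        te = symbolic_te(a, b, 4, delay=2)
        assert 0.0 <= te <= 1.0


class TestEstimateAll:
    def test_candidate_bookkeeping(self, planted_iplv_recording):
        banded = filterbank(planted_iplv_recording)
        scheme = make_windows(340 * 3, banded.fs)
        raw = estimate_all(banded, scheme, estimators=(1, 2, 5))
        for est, arr in raw.items():
            assert arr.shape == (scheme.T, 1, N_CODES + 1)
            admissible = set(ADMISSIBLE_CODES[est])
            for code in range(1, N_CODES + 1):
                col = arr[0, 0, code]
                if code in admissible:
                    assert np.isfinite(col)
                else:
                    assert np.isnan(col)

    def test_planted_pair_maximizes_its_code(self, planted_iplv_recording):
        banded = filterbank(planted_iplv_recording)
        scheme = make_windows(planted_iplv_recording)
        raw = estimate_all(banded, scheme, estimators=(2,))
        full = np.array([b - a == 340 for a, b in
                         zip(scheme.starts, scheme.stops)])
        winners = np.nanargmax(raw[2][full, 0, 1:9], axis=-1) + 1
        alpha1 = dx.within_code("alpha1")
        assert np.mean(winners == alpha1) > 0.9

    def test_all_zero_recording_degenerate(self):
        rec = Recording(np.zeros((2, 1020)), 170.0, ["a", "b"])
        banded = filterbank(rec)
        scheme = make_windows(rec)
        raw = estimate_all(banded, scheme, estimators=(1, 2, 5))
        for arr in raw.values():
            assert np.isnan(arr[:, :, 1:]).all()


class TestDegenerateGuard:
    def test_zero_window_flagged(self):
        rec = Recording(np.zeros((2, 1020)), 170.0, ["a", "b"])
        pre = precompute(filterbank(rec), estimators=(2,))
        val, meta = candidate_strength(pre, slice(0, 340), 0, 1, 2, 3)
        assert np.isnan(val)
        assert meta["degenerate"]
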