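import numpy as np
import pytest
from scipy import signal as sps

from dicmflex.codes import BANDS
from dicmflex.coupling import aec, dpli, iplv
from dicmflex.preprocessing import filterbank
from dicmflex.synthetic_data import (
    AGE_BINS,
    CohortPlan,
    CouplingEntry,
    CouplingPlan,
    age_group_of,
    gen_band_noise,
    gen_cohort,
    gen_recording,
    gen_switching_recording,
)


def _band_power_fraction(x, fs, lo, hi):
    freqs, psd = sps.welch(x, fs=fs, nperseg=min(len(x), 2048))
    total = np.trapezoid(psd, freqs)
    mask = (freqs >= lo) & (freqs <= hi)
    return np.trapezoid(psd[mask], freqs[mask]) / total


class TestBandNoise:
    @pytest.mark.parametrize("band", [(8.0, 10.0), (0.5, 4.0), (30.0, 45.0)])
    def test_power_concentrated_in_band(self, band):
        x = gen_band_noise(band, 170.0, 10.0, seed=1)
        # widen by one Welch bin to absorb spectral leakage
        assert _band_power_fraction(x, 170.0, band[0] - 0.2, band[1] + 0.2) >= 0.9

    def test_zero_mean_unit_variance(self):
        x = gen_band_noise("alpha1", 170.0, 10.0, seed=2)
        assert abs(x.mean()) < 1e-12
        assert x.std() == pytest.approx(1.0)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            gen_band_noise("alpha1", 170.0, 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            gen_band_noise((40.0, 90.0), 170.0, 5.0)

    def test_deterministic_under_seed(self):
        a = gen_band_noise("theta", 170.0, 5.0, seed=7)
        b = gen_band_noise("theta", 170.0, 5.0, seed=7)
        np.testing.assert_array_equal(a, b)


class TestGenRecording:
    def test_background_has_all_bands(self):
        rec = gen_recording(1, 170.0, 10.0, None, seed=3)
        for _, lo, hi in BANDS:
            assert _band_power_fraction(rec.data[0], 170.0, lo, hi) > 0.01

    def test_deterministic_under_seed(self):
        a = gen_recording(3, 170.0, 5.0, None, seed=4)
        b = gen_recording(3, 170.0, 5.0, None, seed=4)
        np.testing.assert_array_equal(a.data, b.data)

    def test_planted_iplv_visible_to_estimator(self, planted_iplv_recording):
        banded = filterbank(planted_iplv_recording)
        val = iplv(banded.phase[2, 0, 340:-340], banded.phase[2, 1, 340:-340])
        assert val > 0.6

    def test_planted_aec_visible_to_estimator(self):
        entry = CouplingEntry((0, 1), "aec", "alpha1", strength=0.9)
        rec = gen_recording(2, 170.0, 20.0, [entry], seed=6)
        banded = filterbank(rec)
        r = aec(banded.envelope[2, 0, 340:-340], banded.envelope[2, 1, 340:-340])
        assert r > 0.5

    def test_planted_dpli_direction(self):
        entry = CouplingEntry((0, 1), "dpli", "alpha2", delay=3)
        rec = gen_recording(2, 170.0, 10.0, [entry], seed=7)
        banded = filterbank(rec)
        v = dpli(banded.phase[3, 0, 340:-340], banded.phase[3, 1, 340:-340])
        assert v > 0.8  # channel 0 leads

    def test_planted_strength_monotonicity(self):
        """Estimated iPLV rises with planted strength (rank correlation)."""
        from scipy.stats import spearmanr

        strengths = np.arange(0.1, 1.0, 0.1)
        est_means = []
        for s in strengths:
            vals = []
            for rep in range(20):
                entry = CouplingEntry((0, 1), "iplv", "alpha1", strength=s)
                rec = gen_recording(2, 170.0, 4.0, [entry], seed=800 + rep)
                banded = filterbank(rec)
                vals.append(iplv(banded.phase[2, 0, 170:-170],
                                 banded.phase[2, 1, 170:-170]))
            est_means.append(np.mean(vals))
        rho, _ = spearmanr(strengths, est_means)
        assert rho > 0.9

    def test_conflicting_entries_rejected(self):
        entries = [CouplingEntry((0, 1), "iplv", "alpha1"),
                   CouplingEntry((1, 0), "aec", "alpha1")]
        with pytest.raises(ValueError, match="conflicting"):
            gen_recording(2, 170.0, 5.0, entries)

    def test_non_overlapping_active_ranges_allowed(self):
        entries = [CouplingEntry((0, 1), "iplv", "alpha1", active=(0.0, 2.0)),
                   CouplingEntry((0, 1), "aec", "alpha1", active=(2.0, 4.0))]
        rec = gen_recording(2, 170.0, 5.0, entries)
        assert rec.n_samples == 850

    def test_invalid_strength_rejected(self):
        with pytest.raises(ValueError, match="strength"):
            gen_recording(2, 170.0, 5.0,
                          [CouplingEntry((0, 1), "iplv", strength=1.5)])

    def test_active_range_restricts_coupling(self):
        entry = CouplingEntry((0, 1), "iplv", "alpha1", strength=0.9,
                              active=(0.0, 5.0))
        rec = gen_recording(2, 170.0, 10.0, [entry], seed=8)
        banded = filterbank(rec)
        active = iplv(banded.phase[2, 0, 200:700], banded.phase[2, 1, 200:700])
        inactive = iplv(banded.phase[2, 0, 1100:1600],
                        banded.phase[2, 1, 1100:1600])
        assert active > 2 * inactive


class TestSwitchingRecording:
    def test_dwell_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="dwell"):
            gen_switching_recording(2, 170.0, 10.0, [CouplingPlan()], 1.0)

    def test_regimes_alternate(self):
        modes = [
            CouplingPlan([CouplingEntry((0, 1), "iplv", "alpha1", strength=0.9)]),
            CouplingPlan([CouplingEntry((0, 1), "iplv", "beta3", strength=0.9)]),
        ]
        rec = gen_switching_recording(2, 170.0, 20.0, modes, dwell_s=5.0, seed=9)
        banded = filterbank(rec)
        # alpha1 coupling present in the first dwell, absent in the second
        a1_first = iplv(banded.phase[2, 0, 100:750], banded.phase[2, 1, 100:750])
        a1_second = iplv(banded.phase[2, 0, 950:1600],
                         banded.phase[2, 1, 950:1600])
        assert a1_first > 2 * a1_second


class TestCohort:
    def test_noiseless_curve_recovered_exactly(self):
        table = gen_cohort(CohortPlan(n=60, noise_sd=0.0, n_features=0), seed=1)
        a, b, c = CohortPlan().fi_curve
        expected = a * table["age"] ** 2 + b * table["age"] + c
        np.testing.assert_allclose(table["fi"], expected, atol=1e-12)

    def test_fi_clamped_to_unit_interval(self):
        plan = CohortPlan(n=500, noise_sd=0.5, n_features=0)
        table = gen_cohort(plan, seed=2)
        assert table["fi"].between(0.0, 1.0).all()

    def test_group_offset_shifts_fi(self):
        hp = gen_cohort(CohortPlan(n=300, n_features=0), seed=3)
        rd = gen_cohort(CohortPlan(n=300, n_features=0, fi_offset=-0.1,
                                   group="RD"), seed=3)
        assert hp["fi"].mean() - rd["fi"].mean() == pytest.approx(0.1, abs=0.02)

    def test_ages_fall_in_reference_bins(self):
        table = gen_cohort(CohortPlan(n=400, n_features=0), seed=4)
        assert table["age"].between(AGE_BINS[0][0], AGE_BINS[-1][1]).all()
        assert set(table["age_group"]) == set(range(6))

    def test_age_group_assignment(self):
        np.testing.assert_array_equal(age_group_of(np.array([8, 13, 20, 30, 40, 55])),
                                      [0, 1, 2, 3, 4, 5])

    def test_feature_shift_separates_groups(self):
        table = gen_cohort(CohortPlan(n=300, feature_shift=2.0), seed=5)
        f0 = table.groupby("age_group")["feat_00"].mean()
        assert (f0.diff().dropna() > 1.0).all()

    def test_deterministic_under_seed(self):
        a = gen_cohort(CohortPlan(n=50), seed=6)
        b = gen_cohort(CohortPlan(n=50), seed=6)
        assert a.equals(b)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortPlan(n=0)
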