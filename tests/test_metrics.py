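import math

import numpy as np
import pytest

from hrvnoise import PARAMETERS, NoiseSpec, Tachogram, hrv_profile, perturb_beats
from hrvnoise.metrics import (
    apen,
    band_powers,
    corr_dim,
    correlation_sums,
    dfa,
    geometric,
    mean_rr_hr,
    nn50_pnn50,
    poincare,
    prsa_dc_ac,
    resample_rr,
    rmssd,
    rpa_metrics,
    sampen,
    sdnn,
    stress_index,
    welch_psd,
)
from oracles import (
    apen_brute,
    corr_sums_brute,
    dfa_brute,
    prsa_brute,
    rpa_brute,
    sampen_brute,
)

from test_synthetic import make_sinusoidal_tachogram


class TestTimeDomain:
    def test_mean_rr_hr(self):
        assert mean_rr_hr(np.full(10, 1000.0)) == (1000.0, 60.0)
        mean_rr, mean_hr = mean_rr_hr(np.array([800.0, 900.0, 1000.0]))
        assert mean_rr == 900.0
        assert mean_hr == pytest.approx(66.6667, abs=1e-3)

    def test_mean_rr_invariant_under_paired_perturbation(self, rng):
        rr = 800.0 + 50 * rng.standard_normal(100)
        pert = rr.copy()
        pert[3] += 7.5
        pert[60] -= 7.5
        assert mean_rr_hr(pert)[0] == pytest.approx(mean_rr_hr(rr)[0], abs=1e-12)

    def test_sdnn(self):
        assert sdnn(np.full(50, 900.0)) == 0.0
        assert sdnn(np.array([900.0, 1000.0, 1100.0])) == pytest.approx(100.0)

    def test_sdnn_sampling(self, rng):
        rr = 900.0 + 50.0 * rng.standard_normal(10_000)
        assert sdnn(rr) == pytest.approx(50.0, abs=1.5)

    def test_rmssd(self):
        assert rmssd(np.full(50, 900.0)) == 0.0
        assert rmssd(np.array([1000.0, 1060.0, 1000.0])) == pytest.approx(60.0)

    def test_nn50_pnn50(self):
        assert nn50_pnn50(np.full(20, 1000.0)) == (0, 0.0)
        nn50, pnn50 = nn50_pnn50(np.array([1000.0, 1060.0, 1000.0, 1010.0]))
        assert nn50 == 2
        assert pnn50 == 50.0

    def test_exact_50ms_difference_not_counted(self):
        assert nn50_pnn50(np.array([1000.0, 1050.0]))[0] == 0

    @pytest.mark.parametrize(
        "fn", [sdnn, rmssd, nn50_pnn50], ids=["sdnn", "rmssd", "nn50"]
    )
    def test_too_few_intervals_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(np.array([800.0]))


class TestGeometric:
    def test_constant_series_single_bin(self):
        hrvti, tinn = geometric(np.full(100, 900.0))
        assert hrvti == 1.0
        assert tinn == 0.0

    def test_two_bin_histogram(self):
        rr = np.concatenate([np.full(200, 900.0), np.full(100, 950.0)])
        hrvti, _ = geometric(rr)
        assert hrvti == pytest.approx(1.5)

    def test_tinn_recovers_triangle_base(self):
        """A histogram whose counts follow an exact triangle of base b yields
        TINN = b to within one bin width."""
        w = 1000.0 / 128.0
        counts = [1, 2, 3, 4, 5, 4, 3, 2, 1]  # feet one bin beyond each end
        rr = np.concatenate(
            [np.full(c, 900.0 + k * w) for k, c in enumerate(counts)]
        )
        _, tinn = geometric(rr)
        assert abs(tinn - 10 * w) <= w


class TestStressIndex:
    def test_hand_constructed_histogram(self):
        """Modal 50-ms bin [900, 950) holds 4 of 10 intervals, so
        Mo = 0.925 s, AMo = 40%, MxDMn = 0.3 s."""
        rr = np.array(
            [850.0, 900, 905, 910, 915, 960, 1010, 1060, 1110, 1150]
        )
        assert stress_index(rr) == pytest.approx(
            math.sqrt(40.0 / (2 * 0.925 * 0.3)), abs=1e-9
        )

    def test_widening_range_lowers_index(self):
        """SI^2 is inversely proportional to MxDMn (all else equal)."""
        rr = np.array([850.0, 900, 905, 910, 915, 960, 1010, 1060, 1110, 1150])
        rr2 = rr.copy()
        rr2[-1] = 1450.0  # doubles MxDMn from 0.3 to 0.6 s, same modal bin
        assert stress_index(rr2) == pytest.approx(
            stress_index(rr) / math.sqrt(2), abs=1e-9
        )

    def test_constant_series_sentinel(self):
        assert math.isnan(stress_index(np.full(20, 900.0)))


class TestPRSA:
    def test_alternating_series_zero_capacity(self):
        rr = np.array([1000.0, 1050.0] * 10)
        dc, dcmod, ac, acmod = prsa_dc_ac(rr)
        assert dc == pytest.approx(0.0, abs=1e-12)
        assert ac == pytest.approx(0.0, abs=1e-12)
        assert dcmod == pytest.approx(25.0)
        assert acmod == pytest.approx(-25.0)

    def test_monotone_ramp(self):
        rr = np.array([1000.0, 1010.0, 1020.0, 1030.0, 1040.0])
        dc, dcmod, ac, acmod = prsa_dc_ac(rr)
        assert dc == pytest.approx(10.0)
        assert dcmod == pytest.approx(5.0)
        assert math.isnan(ac) and math.isnan(acmod)

    def test_large_relative_changes_excluded(self):
        # a 10% jump is not a valid anchor
        rr = np.array([1000.0, 1100.0, 1000.0, 1100.0, 1000.0])
        out = prsa_dc_ac(rr)
        assert all(math.isnan(v) for v in out)

    def test_oracle_equivalence(self, rng):
        rr = 900.0 + 30.0 * rng.standard_normal(200)
        ours = prsa_dc_ac(rr)
        ref = prsa_brute(rr)
        np.testing.assert_allclose(ours, ref, atol=1e-9)


class TestSpectral:
    def test_constant_rr_zero_after_mean_removal(self):
        tach = Tachogram.from_rr(np.full(400, 900.0))
        _, sig = resample_rr(tach)
        assert np.allclose(sig, 900.0)
        est = welch_psd(sig)
        assert np.allclose(est.psd, 0.0)

    def test_linear_trend_reproduced(self):
        rr = np.linspace(800.0, 900.0, 400)
        tach = Tachogram.from_rr(rr)
        grid, sig = resample_rr(tach)
        expected = np.interp(grid, tach.beat_times[1:], rr)
        np.testing.assert_allclose(sig, expected, atol=1e-6)

    def test_sinusoid_power_in_hf_band(self):
        t = np.arange(1200) / 4.0  # 300 s at 4 Hz
        sig = 20.0 * np.sin(2 * np.pi * 0.25 * t)
        bp = band_powers(welch_psd(sig))
        assert bp["HFpower"] == pytest.approx(200.0, abs=10.0)
        assert bp["LFpower"] < 10.0
        assert bp["LF/HF"] < 0.05

    def test_white_signal_parseval(self, rng):
        sig = rng.standard_normal(2400) * 30.0
        bp = band_powers(welch_psd(sig))
        # one-sided PSD over 0-2 Hz; the 0-0.4 Hz bands hold ~1/5 of the power
        total_psd = welch_psd(sig)
        full = np.trapezoid(total_psd.psd, total_psd.freqs)
        assert full == pytest.approx(sig.var(), rel=0.10)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter than one"):
            welch_psd(np.zeros(100))

    def test_normalized_units_sum_to_100(self, one_segment):
        _, sig = resample_rr(one_segment.tachogram)
        bp = band_powers(welch_psd(sig))
        assert bp["nLF"] + bp["nHF"] == 100.0

    def test_equal_tones_give_unit_ratio(self):
        t = np.arange(1200) / 4.0
        sig = 20 * np.sin(2 * np.pi * 0.1 * t) + 20 * np.sin(2 * np.pi * 0.3 * t)
        bp = band_powers(welch_psd(sig))
        assert bp["LF/HF"] == pytest.approx(1.0, abs=0.1)


class TestPoincare:
    def test_constant(self):
        sd1, sd2, ratio = poincare(np.full(20, 900.0))
        assert sd1 == 0.0 and sd2 == 0.0
        assert math.isnan(ratio)

    def test_alternating(self):
        rr = np.array([975.0, 1025.0] * 20)
        sd1, sd2, _ = poincare(rr)
        assert sd1 == pytest.approx(50.0 / math.sqrt(2))
        assert sd2 == pytest.approx(0.0, abs=1e-9)

    def test_sd1_rmssd_identity(self, rng):
        rr = 900.0 + 40 * rng.standard_normal(300)
        sd1, _, _ = poincare(rr)
        assert sd1 == pytest.approx(rmssd(rr) / math.sqrt(2), rel=1e-12)


class TestEntropies:
    def test_constant_series_zero(self):
        rr = np.full(50, 900.0)
        assert apen(rr) == pytest.approx(0.0, abs=1e-12)
        assert sampen(rr) == pytest.approx(0.0, abs=1e-12)

    def test_apen_oracle(self, rng):
        rr = 900.0 + 30 * rng.standard_normal(50)
        r = 0.2 * np.std(rr, ddof=1)
        assert apen(rr) == pytest.approx(apen_brute(rr, 2, r), abs=1e-9)

    def test_sampen_oracle(self, rng):
        rr = 900.0 + 30 * rng.standard_normal(50)
        r = 0.2 * np.std(rr, ddof=1)
        assert sampen(rr) == pytest.approx(sampen_brute(rr, 2, r), abs=1e-9)

    def test_periodic_below_shuffled(self, rng):
        periodic = np.array([900.0, 950.0] * 100)
        shuffled = rng.permutation(periodic + rng.normal(0, 5, 200))
        assert apen(periodic) < apen(shuffled)

    def test_ramp_with_tight_tolerance_flagged(self):
        rr = np.linspace(800.0, 1200.0, 60)
        assert math.isnan(sampen(rr, r=1e-6))


class TestDFA:
    def test_white_noise_alpha_half(self, rng):
        rr = 900.0 + 30 * rng.standard_normal(5000)
        a1, a2 = dfa(rr)
        assert a1 == pytest.approx(0.5, abs=0.1)
        assert a2 == pytest.approx(0.5, abs=0.1)

    def test_brownian_alpha_three_halves(self, rng):
        rr = 900.0 + np.cumsum(rng.standard_normal(5000))
        a1, _ = dfa(rr)
        assert a1 == pytest.approx(1.5, abs=0.15)

    def test_oracle_equivalence(self, rng):
        rr = 900.0 + 30 * rng.standard_normal(200)
        a1, a2 = dfa(rr)
        assert a1 == pytest.approx(dfa_brute(rr, 4, 16), abs=1e-9)
        assert a2 == pytest.approx(dfa_brute(rr, 16, 64), abs=1e-9)

    def test_short_series_sentinels(self):
        a1, a2 = dfa(np.full(80, 900.0) + np.arange(80))
        assert math.isnan(a1) and math.isnan(a2)


class TestCorrelationDimension:
    def test_single_tone_attractor_dimension_one(self):
        tach = make_sinusoidal_tachogram(amp_ms=50.0, freq_hz=0.1, n_beats=400)
        assert corr_dim(tach.rr) == pytest.approx(1.0, abs=0.3)

    def test_iid_series_higher_dimensional(self, rng):
        tach = make_sinusoidal_tachogram(amp_ms=50.0, freq_hz=0.1, n_beats=400)
        iid = 900.0 + 30 * rng.standard_normal(400)
        assert corr_dim(iid) > corr_dim(tach.rr)

    def test_constant_sentinel(self):
        assert math.isnan(corr_dim(np.full(300, 900.0)))

    def test_correlation_sums_oracle(self, rng):
        rr = 900.0 + 30 * rng.standard_normal(60)
        radii = np.geomspace(5.0, 300.0, 8)
        ours = correlation_sums(rr, radii, m=10, tau=1)
        ref = corr_sums_brute(rr, radii, 10, 1)
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestRPA:
    def test_oracle_equivalence(self, rng):
        rr = 900.0 + 30 * rng.standard_normal(30)
        r = math.sqrt(10) * np.std(rr, ddof=1)
        ours = rpa_metrics(rr, m=10, tau=1)
        ref = rpa_brute(rr, 10, 1, r)
        np.testing.assert_allclose(ours, ref, atol=1e-9)

    def test_fully_recurrent_series(self):
        rr = np.full(40, 900.0)
        rec, det, lmean, lmax, shanen = rpa_metrics(rr)
        nv = 40 - 9  # embedded vectors
        assert rec == 100.0
        assert det == pytest.approx(100.0, abs=0.5)
        assert lmax == nv - 1  # longest off-identity diagonal

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            rpa_metrics(np.full(15, 900.0))


class TestProfile:
    def test_exactly_34_named_parameters(self, one_segment):
        prof = hrv_profile(one_segment)
        assert tuple(prof.values) == PARAMETERS
        assert len(prof.values) == 34

    def test_deterministic(self, one_segment):
        a, b = hrv_profile(one_segment), hrv_profile(one_segment)
        assert a.values == b.values

    def test_synthetic_segment_has_no_sentinels(self, one_segment):
        prof = hrv_profile(one_segment)
        assert prof.sentinels == {}
        assert all(np.isfinite(v) for v in prof.values.values())

    def test_parameter_subset(self, one_segment):
        prof = hrv_profile(one_segment, ("SDNN", "LF/HF"))
        assert tuple(prof.values) == ("SDNN", "LF/HF")

    def test_unknown_parameter_rejected(self, one_segment):
        with pytest.raises(ValueError, match="unknown parameters"):
            hrv_profile(one_segment, ("SDNN", "XYZ"))

    def test_degenerate_segment_flagged_not_silent(self):
        tach = Tachogram.from_rr(np.full(30, 900.0))
        prof = hrv_profile(tach)
        assert math.isnan(prof["SI"])
        assert "SI" in prof.sentinels

    def test_near_zero_noise_leaves_profile_unchanged(self, one_segment):
        clean = hrv_profile(one_segment)
        noisy_tach = perturb_beats(
            one_segment.tachogram, NoiseSpec("gaussian", 1e-9, seed=17)
        )
        noisy = hrv_profile(noisy_tach)
        for p in PARAMETERS:
            ref = clean[p]
            tol = 1e-6 * max(abs(ref), 1.0)
            assert abs(noisy[p] - ref) <= tol, p
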