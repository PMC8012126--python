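import numpy as np
import pytest

import ilfs_ecg as m
from ilfs_ecg.exceptions import TrialInvalidError
from ilfs_ecg.hrv_features import (
    FEATURE_NAMES,
    extract_all,
    frequency_domain,
    lz76_phrase_count,
    lz_complexity,
    poincare,
    time_domain,
)
from ilfs_ecg.rpeak import RRSeries

from _oracles import poincare_oracle, time_domain_oracle


def _random_rr(rng, n=None):
    n = n or rng.integers(8, 40)
    return rng.uniform(500.0, 1200.0, size=n)


def _rrseries_from_rr(rr):
    beats = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    return RRSeries(peak_times=beats, rr=np.asarray(rr, float), rr_times=beats[1:])


class TestTimeDomain:
    def test_constant_series(self):
        f = time_domain(np.full(5, 800.0))
        assert f["Mean_RR"] == 800.0 and f["SDRR"] == 0.0 and f["RMSSD"] == 0.0
        assert f["NN50"] == 0 and f["QD"] == 0.0 and f["Mean_HR"] == 75.0

    def test_hand_computed_example(self):
        f = time_domain(np.array([800.0, 860.0, 790.0, 855.0]))
        # d = [60, -70, 65]
        assert f["NN50"] == 3 and f["PNN50"] == 100.0
        assert f["NN20"] == 3 and f["MSD"] == 65.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            rr = _random_rr(rng)
            got = time_domain(rr)
            want = time_domain_oracle(rr)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, rel=1e-9), k

    def test_nn20_at_least_nn50(self, rng):
        for _ in range(20):
            f = time_domain(_random_rr(rng))
            assert f["NN20"] >= f["NN50"]

    def test_too_short_series_invalid(self):
        with pytest.raises(TrialInvalidError):
            time_domain(np.array([800.0, 810.0, 790.0]))


class TestPoincare:
    def test_constant_series_degenerate(self):
        f = poincare(np.full(6, 800.0))
        assert f["SD1"] == 0.0 and f["SD2"] == 0.0
        assert np.isnan(f["CSI"]) and np.isnan(f["CVI"]) and np.isnan(f["Modified_CSI"])

    def test_alternating_series_sd1(self):
        # successive differences alternate +/-100 ms, so sd1 ~ 100/sqrt(2)
        rr = np.tile([800.0, 900.0], 10)
        assert poincare(rr)["SD1"] == pytest.approx(100.0 / np.sqrt(2.0), rel=1e-2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            rr = _random_rr(rng)
            got = poincare(rr)
            want = poincare_oracle(rr)
            for k, v in want.items():
                assert got[k] == pytest.approx(v, rel=1e-9), k

    def test_rotation_identity(self, rng):
        for _ in range(20):
            rr = _random_rr(rng)
            f = poincare(rr)
            sdrr = np.std(rr, ddof=1)
            assert f["SD1"] ** 2 + f["SD2"] ** 2 == pytest.approx(2 * sdrr**2, rel=1e-9)

    def test_sd1_equals_population_sdsd_over_sqrt2(self, rng):
        for _ in range(20):
            rr = _random_rr(rng)
            sdsd_pop = np.std(np.diff(rr), ddof=0)
            assert poincare(rr)["SD1"] == pytest.approx(sdsd_pop / np.sqrt(2.0), rel=1e-9)


class TestScaleEquivariance:
    @pytest.mark.parametrize("k", [0.5, 2.0, 3.7])
    def test_scaling_behaviour(self, rng, k):
        rr = _random_rr(rng, n=30)
        base = {**time_domain(rr), **poincare(rr)}
        scaled = {**time_domain(rr * k), **poincare(rr * k)}
        for name in ("Mean_RR", "SDRR", "RMSSD", "MSD", "SDSD", "QD", "SD1", "SD2"):
            assert scaled[name] == pytest.approx(k * base[name], rel=1e-9)
        for name in ("CVRR", "SD1_SD2"):
            assert scaled[name] == pytest.approx(base[name], rel=1e-9)
        assert scaled["Mean_HR"] == pytest.approx(base["Mean_HR"] / k, rel=1e-9)


class TestLZComplexity:
    def test_classic_sequence_phrase_count(self):
        # exhaustive-history parsing 0|001|10|100|1000|101 -> 6 phrases
        assert lz76_phrase_count("0001101001000101") == 6

    def test_constant_sequence_minimal_complexity(self):
        n = 16
        assert lz76_phrase_count([1] * n) == 2
        assert lz_complexity(np.full(n, 800.0)) == pytest.approx(2 * np.log2(n) / n)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_sequence_normalization(self, seed):
        rr = np.random.default_rng(seed).uniform(500, 1200, size=512)
        assert 0.8 <= lz_complexity(rr) <= 1.2

    def test_invariant_to_monotone_transform(self, rng):
        rr = _random_rr(rng, n=64)
        assert lz_complexity(rr) == lz_complexity(np.exp(rr / 400.0))

    def test_too_short_series_invalid(self):
        with pytest.raises(TrialInvalidError):
            lz_complexity(np.full(7, 800.0))


class TestFrequencyDomain:
    def test_band_fractions_normalize(self, rng):
        rrs = _rrseries_from_rr(_random_rr(rng, n=20))
        f = frequency_domain(rrs)
        assert f["nLFP"] + f["nHFP"] == pytest.approx(1.0)

    def test_band_powers_add_to_total(self, rng):
        rrs = _rrseries_from_rr(_random_rr(rng, n=20))
        f = frequency_domain(rrs)
        assert abs(f["TP"] - (f["LF"] + f["HF"])) / f["TP"] < 1e-9

    def test_pure_hf_tone_dominates_hf_band(self):
        beats, t = [0.0], 0.0
        while t < 120.0:
            rr = 800.0 + 30.0 * np.sin(2 * np.pi * 0.25 * t)
            t += rr / 1000.0
            beats.append(t)
        beats = np.array(beats)
        rrs = RRSeries(beats, np.diff(beats) * 1000.0, beats[1:])
        assert frequency_domain(rrs)["nHFP"] >= 0.9

    def test_too_short_span_invalid(self):
        rrs = _rrseries_from_rr(np.full(4, 500.0))  # spans only 2 s
        with pytest.raises(TrialInvalidError):
            frequency_domain(rrs)


class TestExtractAll:
    def test_vector_length_and_order(self, rng):
        vec = extract_all(_rrseries_from_rr(_random_rr(rng, n=15)))
        assert vec.shape == (25,)
        assert len(FEATURE_NAMES) == 25

    def test_constant_trial_gives_zero_dispersion_and_nan_ratios(self):
        vec = extract_all(_rrseries_from_rr(np.full(12, 800.0)))
        named = dict(zip(FEATURE_NAMES, vec))
        assert named["SDRR"] == 0.0 and named["RMSSD"] == 0.0
        assert np.isnan(named["CSI"]) and np.isnan(named["SD1_SD2"])

    def test_mean_rr_recovered_through_full_signal_path(self):
        rr = m.generate_rr_series(14, 780.0, 20.0, seed=2)
        rec, _ = m.render_ecg(rr, fs=1000.0, noise_sd=0.02, seed=4)
        ds = m.downsample(rec, 200.0)
        den = m.denoise_dwt(ds.samples, 200.0)
        peaks = m.pan_tompkins(den, 200.0)
        rrs = m.to_rr(peaks, 200.0)
        vec = extract_all(rrs)
        assert abs(vec[0] - 780.0) <= 10.0
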