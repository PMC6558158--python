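"""Attenuation coefficient, harmonic ratio, coherence, phase difference."""

import numpy as np
import pytest
from scipy.signal import coherence as scipy_coherence

import headgait as hg
from headgait import spectral as hspec
from headgait import stability as hstab

FS = 100.0
DF = FS / 512.0


def _make_spectrum(power):
    freqs = np.arange(len(power)) * DF
    return hspec.StepSpectrum(
        freqs=freqs, power=np.asarray(power, dtype=float),
        segment_length=512, window="blackman", center_index=0,
    )


class TestAttenuationCoefficient:
    @pytest.mark.parametrize(
        "rms_head, rms_trunk, expected",
        [(0.3, 0.3, 0.0), (0.15, 0.3, 0.5), (0.6, 0.3, -1.0)],
    )
    def test_definition(self, rms_head, rms_trunk, expected):
        assert hg.attenuation_coefficient(rms_head, rms_trunk) == (
            pytest.approx(expected)
        )

    def test_zero_trunk_rms_undefined(self):
        assert np.isnan(hg.attenuation_coefficient(0.1, 0.0))

    def test_never_exceeds_one(self, rng):
        for _ in range(100):
            ac = hg.attenuation_coefficient(rng.uniform(0, 2), rng.uniform(0.01, 2))
            assert ac <= 1.0


class TestHarmonicRatio:
    def test_even_only_power_hits_cap(self):
        power = np.zeros(257)
        f_dom = 16 * DF  # 3.125 Hz, so the stride base 8·DF is on-grid
        for k in range(1, 11):
            b = 16 * k
            if b < power.size:
                power[b] = 1.0
        spec = _make_spectrum(power)
        assert hg.harmonic_ratio(spec, f_dom, "V") == 100.0
        assert hg.harmonic_ratio(spec, f_dom, "ML") == pytest.approx(0.0)

    def test_equal_power_everywhere_gives_one(self):
        spec = _make_spectrum(np.ones(257))
        f_dom = 16 * DF
        assert hg.harmonic_ratio(spec, f_dom, "AP") == pytest.approx(1.0)
        assert hg.harmonic_ratio(spec, f_dom, "ML") == pytest.approx(1.0)

    def test_four_to_one_matches_bin_sum_oracle(self):
        # even power 4 per harmonic, odd power 1: HR = 4 (AP/V), 0.25 (ML)
        power = np.zeros(257)
        f_dom = 16 * DF
        even_bins = [16 * k for k in range(1, 11) if 16 * k < 257]
        odd_bins = [8 * (2 * k - 1) for k in range(1, 11) if 8 * (2 * k - 1) < 257]
        for b in even_bins:
            power[b] = 4.0
        for b in odd_bins:
            power[b] += 1.0
        spec = _make_spectrum(power)
        e = sum(power[b] for b in even_bins)  # brute-force bin sums
        o_only = 1.0 * len(odd_bins)
        # even bins that coincide with odd bins do not exist here (8·odd is
        # never a multiple of 16), so the oracle ratio is exact
        assert hg.harmonic_ratio(spec, f_dom, "V") == pytest.approx(
            e / o_only, abs=1e-9
        )
        assert hg.harmonic_ratio(spec, f_dom, "ML") == pytest.approx(
            o_only / e, abs=1e-9
        )

    def test_harmonics_truncated_at_nyquist(self):
        power = np.ones(257)
        f_dom = 40 * DF  # 7.8 Hz; only 6 even harmonics fit below 50 Hz
        assert np.isfinite(hg.harmonic_ratio(_make_spectrum(power), f_dom, "V"))

    def test_invalid_f_dom_gives_nan(self):
        assert np.isnan(hg.harmonic_ratio(_make_spectrum(np.ones(257)),
                                          float("nan"), "V"))

    def test_session_hr_targets_qualitative(self, noiseless_result):
        df = noiseless_result.steps
        # generator injects even:odd power 4:1 vertically and 1:2.5 in ML
        assert df["hr_trunk_V"].median() == pytest.approx(4.0, rel=0.15)
        assert df["hr_trunk_ML"].median() == pytest.approx(0.4, rel=0.2)


class TestCoherence:
    def test_linear_dependence_gives_one(self, rng):
        x = rng.normal(size=4096)
        got = hg.coherence_at_fdom(x, 3.0 * x, 2048, 2.0)
        assert got == pytest.approx(1.0, abs=1e-6)

    def test_matches_scipy_welch(self, rng):
        x = rng.normal(size=4096)
        y = 0.5 * x + rng.normal(size=4096)
        center = 2048
        f, cxy = scipy_coherence(
            x[center - 512 : center + 512], y[center - 512 : center + 512],
            fs=FS, window="blackman", nperseg=512, noverlap=384, detrend=False,
        )
        for f_dom in (1.5, 2.0, 3.1):
            k = int(round(f_dom / DF))
            got = hg.coherence_at_fdom(x, y, center, f_dom)
            assert got == pytest.approx(cxy[k], abs=1e-9)

    def test_independent_noise_bias_matches_monte_carlo_oracle(self):
        # overlapped 5-segment Welch has a known positive bias under
        # independence; reproduce it with scipy as the brute-force oracle
        rng = np.random.default_rng(77)
        mine, oracle = [], []
        for _ in range(200):
            x = rng.normal(size=1024)
            y = rng.normal(size=1024)
            mine.append(hg.coherence_at_fdom(x, y, 512, 2.0))
            _, cxy = scipy_coherence(
                x, y, fs=FS, window="blackman", nperseg=512, noverlap=384,
                detrend=False,
            )
            oracle.append(cxy[int(round(2.0 / DF))])
        assert np.mean(mine) == pytest.approx(np.mean(oracle), abs=1e-9)
        assert np.mean(mine) > 0.1  # the bias is distinctly positive

    def test_bounded_in_unit_interval(self, noiseless_result):
        coh = noiseless_result.steps[["coh_hp_hv", "coh_hp_tp"]].to_numpy()
        coh = coh[np.isfinite(coh)]
        assert np.all(coh >= 0.0) and np.all(coh <= 1.0)

    def test_session_phase_locked_coherence(self, noiseless_result):
        df = noiseless_result.steps
        assert df["coh_hp_hv"].median() >= 0.99
        assert df["coh_hp_tp"].median() >= 0.99

    def test_zero_power_undefined(self):
        x = np.zeros(2048)
        assert np.isnan(hg.coherence_at_fdom(x, x, 1024, 2.0))


class TestPhaseDifference:
    def test_identical_sinusoids_corrected_to_minus_half_pi(self):
        t = np.arange(4096) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        got = hg.phase_difference(x, x, 2048)
        assert got == pytest.approx(-np.pi / 2, abs=np.deg2rad(1.0))

    def test_quarter_period_delay(self):
        t = np.arange(4096) / FS
        f0 = 2.0
        x = np.sin(2 * np.pi * f0 * t)
        y = np.sin(2 * np.pi * f0 * (t - 0.25 / f0))  # y delayed
        got = hg.phase_difference(x, y, 2048)
        assert got == pytest.approx(-np.pi, abs=np.deg2rad(2.0))

    def test_random_offsets_recovered(self, rng):
        f0 = 1.9
        t = np.arange(4096) / FS
        for _ in range(10):
            phi = rng.uniform(-2.0, 2.0)
            x = np.sin(2 * np.pi * f0 * t)
            y = np.sin(2 * np.pi * f0 * t + phi)
            got = hg.phase_difference(x, y, 2048, correction=0.0)
            assert hstab.wrap_phase(got - phi) == pytest.approx(
                0.0, abs=2 * np.pi * f0 / FS
            )

    def test_aperiodic_input_undefined(self):
        x = np.full(4096, 0.7)  # constant: no oscillation to take a period from
        y = np.sin(np.arange(4096))
        assert np.isnan(hg.phase_difference(x, y, 2048))

    def test_phases_wrapped(self, noiseless_result):
        ph = noiseless_result.steps[["phase_hv_hp", "phase_hv_tp"]].to_numpy()
        ph = ph[np.isfinite(ph)]
        assert np.all(ph > -np.pi) and np.all(ph <= np.pi)


class TestScaleInvariance:
    def test_all_measures_scale_invariant(self, rng):
        t = np.arange(4096) / FS
        x = np.sin(2 * np.pi * 1.9 * t) + 0.1 * rng.normal(size=4096)
        y = np.sin(2 * np.pi * 1.9 * t + 0.7) + 0.1 * rng.normal(size=4096)
        c = 37.5
        assert hg.attenuation_coefficient(
            hspec.segment_rms(c * x, 2048, 512), hspec.segment_rms(c * y, 2048, 512)
        ) == pytest.approx(
            hg.attenuation_coefficient(
                hspec.segment_rms(x, 2048, 512), hspec.segment_rms(y, 2048, 512)
            ),
            abs=1e-12,
        )
        s1 = hspec.step_spectrum(x, 2048, 512)
        s2 = hspec.step_spectrum(c * x, 2048, 512)
        assert hg.harmonic_ratio(s1, 1.953125, "V") == pytest.approx(
            hg.harmonic_ratio(s2, 1.953125, "V"), abs=1e-9
        )
        assert hg.coherence_at_fdom(c * x, y, 2048, 1.9) == pytest.approx(
            hg.coherence_at_fdom(x, y, 2048, 1.9), abs=1e-9
        )
        assert hg.phase_difference(c * x, y / c, 2048) == pytest.approx(
            hg.phase_difference(x, y, 2048), abs=1e-9
        )
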