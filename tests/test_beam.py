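"""Beam arithmetic, flux geometry and injection sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from flashchem.beam import (BeamSpotPattern, PulseStructure, ROIGeometry,
                            beam_table, cdr_flux, diffusion_span_um,
                            flux_at_pattern_center, instantaneous_rate,
                            mean_extraction_rate, peak_flux,
                            protons_per_micropulse,
                            sample_injection_schedule)


class TestClosedFormChain:
    def test_mean_extraction_rate_reference(self):
        assert mean_extraction_rate(4.96, 50.0) == pytest.approx(6.20e8,
                                                                 rel=1e-3)

    def test_single_proton_identity(self):
        # one elementary charge extracted over 1 ms is one proton per ms
        assert mean_extraction_rate(1.6e-19 * 1e9, 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("charge,width", [(0.0, 50.0), (4.96, 0.0),
                                              (-1.0, 50.0)])
    def test_nonpositive_inputs_rejected(self, charge, width):
        with pytest.raises(ValueError):
            mean_extraction_rate(charge, width)

    def test_instantaneous_rate_scales_by_duty_cycle(self, pulse):
        assert instantaneous_rate(0.0, pulse) == 0.0
        r = instantaneous_rate(6.20e8, pulse)
        assert r == pytest.approx(6.20e8 * 143.0 / 24.0)
        with pytest.raises(ValueError):
            instantaneous_rate(-1.0, pulse)

    def test_peak_flux_gaussian_normalisation(self):
        assert peak_flux(0.0, 3.0) == 0.0
        with pytest.raises(ValueError):
            peak_flux(1.0, 0.0)

    def test_peak_flux_quadrature_oracle(self):
        """2-D integral of the Gaussian flux profile recovers the rate."""
        rate = 3.69e9
        sigma_cm = 0.3
        psi = peak_flux(rate, 3.0)
        val, _ = integrate.quad(
            lambda r: psi * math.exp(-r * r / (2 * sigma_cm ** 2))
            * 2 * math.pi * r, 0.0, 20 * sigma_cm)
        assert val == pytest.approx(rate, rel=1e-6)

    def test_pattern_center_attenuation(self):
        psi = 6.53e9
        assert flux_at_pattern_center(psi, 0.0, 3.0) == psi
        # direct evaluation of exp(-(a/sqrt2)^2 / 2 sigma^2)
        expected = psi * math.exp(-12.5 / 18.0)
        assert flux_at_pattern_center(psi, 5.0, 3.0) == pytest.approx(
            expected, rel=1e-12)

    def test_protons_per_micropulse(self, pulse):
        roi = ROIGeometry()
        assert protons_per_micropulse(0.0, roi, pulse) == 0.0
        n = protons_per_micropulse(3.26e9, roi, pulse)
        assert n == pytest.approx(3.26e9 * 2.5e-5 * 2.4e-5, rel=1e-12)

    def test_cdr_flux(self):
        assert cdr_flux(6.53e9, 726.3) == pytest.approx(8.99e6, rel=1e-3)
        assert cdr_flux(42.0, 1.0) == 42.0
        with pytest.raises(ValueError):
            cdr_flux(1.0, 0.0)

    def test_beam_table_consistency(self):
        t = beam_table()
        # the table chains the individual operations consistently
        assert t["center_flux_cm2ms"] < t["peak_flux_cm2ms"]
        assert t["cdr_protons_per_micropulse"] == pytest.approx(
            t["protons_per_micropulse"] / 726.3, rel=1e-12)
        assert t["mean_interproton_interval_us"] == pytest.approx(
            0.143 / t["cdr_protons_per_micropulse"], rel=1e-12)


class TestDiffusionSpan:
    def test_hydroxyl_span_over_one_pulse(self):
        assert diffusion_span_um(2.8e9, 50.0) == pytest.approx(16.733,
                                                               abs=1e-3)

    def test_zero_time(self):
        assert diffusion_span_um(2.8e9, 0.0) == 0.0

    def test_brownian_monte_carlo_oracle(self, rng):
        """Empirical RMS of 1-D Brownian paths matches sqrt(2 D t)."""
        d_nm2_s, t_ms, n = 2.8e9, 1.0, 4000
        sigma_nm = math.sqrt(2 * d_nm2_s * t_ms * 1e-3)
        x = rng.normal(0.0, sigma_nm, size=n)  # exact endpoint distribution
        msd = np.mean(x ** 2)
        se = math.sqrt(2.0 / n) * sigma_nm ** 2
        assert abs(msd - sigma_nm ** 2) < 3 * se
        assert diffusion_span_um(d_nm2_s, t_ms) * 1e3 == pytest.approx(
            sigma_nm)


class TestInjectionSampling:
    def test_integer_density_counts_and_windows(self, pulse, rng):
        roi = ROIGeometry()
        sched = sample_injection_schedule(10, 2, roi, pulse, rng)
        assert len(sched) == 20
        t = np.asarray(sched.times_ns)
        k = np.floor(t / pulse.micropulse_period_ns)
        offset = t - k * pulse.micropulse_period_ns
        assert np.all(offset >= 0)
        assert np.all(offset < pulse.micropulse_width_ns)
        assert np.all(np.diff(t) >= 0)
        xy = np.asarray(sched.entry_xy_nm)
        assert np.all((xy >= 0) & (xy < roi.face_side_nm))

    def test_fractional_density_binomial_oracle(self, pulse):
        roi = ROIGeometry()
        n_mp, p = 1000, 0.5
        sched = sample_injection_schedule(n_mp, p, roi, pulse,
                                          np.random.default_rng(7))
        sd = math.sqrt(n_mp * p * (1 - p))
        assert abs(len(sched) - n_mp * p) < 3 * sd
        # fraction of empty micropulses ~ 1 - p
        k = np.unique(np.floor(np.asarray(sched.times_ns)
                               / pulse.micropulse_period_ns))
        empty_frac = 1 - k.size / n_mp
        assert abs(empty_frac - (1 - p)) < 3 * sd / n_mp

    def test_fixed_seed_reproducible(self, pulse):
        roi = ROIGeometry()
        a = sample_injection_schedule(5, 1, roi, pulse, 42)
        b = sample_injection_schedule(5, 1, roi, pulse, 42)
        assert np.array_equal(a.times_ns, b.times_ns)
        assert np.array_equal(a.entry_xy_nm, b.entry_xy_nm)

    @pytest.mark.parametrize("n_mp,n_per", [(0, 2), (10, 0.0), (10, 2e4),
                                            (10, 2.5)])
    def test_invalid_parameters(self, pulse, n_mp, n_per):
        with pytest.raises(ValueError):
            sample_injection_schedule(n_mp, n_per, ROIGeometry(), pulse, 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n_mp=st.integers(1, 20), n_per=st.integers(1, 3),
           seed=st.integers(0, 2 ** 16))
    def test_times_always_inside_micropulse_windows(self, n_mp, n_per, seed):
        pulse = PulseStructure()
        sched = sample_injection_schedule(n_mp, n_per, ROIGeometry(), pulse,
                                          seed)
        t = np.asarray(sched.times_ns)
        assert len(sched) == n_mp * n_per
        offset = np.mod(t, pulse.micropulse_period_ns)
        assert np.all(offset < pulse.micropulse_width_ns)


class TestDomainTypes:
    def test_pulse_invariants(self):
        with pytest.raises(ValueError):
            PulseStructure(micropulse_width_ns=150.0,
                           micropulse_period_ns=143.0)

    def test_spot_pattern_invariants(self):
        with pytest.raises(ValueError):
            BeamSpotPattern(sigma_mm=-1.0)
        with pytest.raises(ValueError):
            BeamSpotPattern(uhdr_dose_rate_gy_s=0.5, cdr_dose_rate_gy_s=1.0)

    def test_roi_box(self):
        roi = ROIGeometry(face_side_um=10.0, depth_um=2.0)
        assert roi.box_nm == (10000.0, 10000.0, 2000.0)
        assert roi.volume_nm3 == pytest.approx(2e11)
        with pytest.raises(ValueError):
            ROIGeometry(face_side_um=0.0)
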