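"""Unit and property tests for the simulated measurement chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virtuchlor import (
    Band,
    DetectorConfig,
    Instrument,
    LEDSource,
    OpticalSample,
    SpadLikeParams,
    adc_read,
    average_filter,
    cci,
    log_index,
    percent_transmission,
    scan,
    spad_like,
    zero_calibrate,
)
from virtuchlor.meter_core import (
    CalibrationError,
    CalibrationMissingError,
    TransmittanceDomainError,
)


class TestIndexArithmetic:
    @pytest.mark.parametrize(
        "v_sample, v_air, expected",
        [(2.3, 4.6, 0.5), (4.6, 4.6, 1.0), (1.15, 4.6, 0.25)],
    )
    def test_percent_transmission(self, v_sample, v_air, expected):
        assert percent_transmission(v_sample, v_air) == pytest.approx(expected)

    def test_percent_transmission_requires_air_reference(self):
        with pytest.raises(CalibrationMissingError):
            percent_transmission(1.0, 0.0)

    @pytest.mark.parametrize(
        "t_ir, t_red, expected", [(0.5, 0.05, 10.0), (0.8, 0.8, 1.0), (0.9, 0.3, 3.0)]
    )
    def test_cci_ratio(self, t_ir, t_red, expected):
        assert cci(t_ir, t_red) == pytest.approx(expected)

    def test_cci_domain_error_names_band(self):
        with pytest.raises(TransmittanceDomainError) as err:
            cci(0.0, 0.5)
        assert err.value.band is Band.NIR
        with pytest.raises(TransmittanceDomainError) as err:
            cci(0.5, -0.1)
        assert err.value.band is Band.RED

    @pytest.mark.parametrize(
        "t_ir, t_red, expected",
        [(0.5, 0.05, 1.0), (0.8, 0.8, 0.0), (0.03, 0.0585, math.log10(0.03 / 0.0585))],
    )
    def test_log_index(self, t_ir, t_red, expected):
        assert log_index(t_ir, t_red) == pytest.approx(expected, abs=1e-12)

    def test_log_index_reaches_low_lemon_output(self):
        # A pale sample transmitting more red than NIR gives a negative index.
        assert round(log_index(0.03, 0.0585), 2) == -0.29

    @pytest.mark.parametrize(
        "k, c, expected", [(1.0, 0.0, 1.0), (2.0, 3.0, 5.0)]
    )
    def test_spad_like_affine_map(self, k, c, expected):
        assert spad_like(0.5, 0.05, SpadLikeParams(k=k, C=c)) == pytest.approx(expected)

    def test_spad_like_offset_only_on_identity_sample(self):
        assert spad_like(0.8, 0.8, SpadLikeParams(k=17.0, C=-2.5)) == pytest.approx(-2.5)

    @settings(max_examples=200, derandomize=True)
    @given(
        t_ir=st.floats(1e-6, 1.0),
        t_red=st.floats(1e-6, 1.0),
        k=st.floats(-50, 50),
        c=st.floats(-50, 50),
    )
    def test_spad_like_defaults_reduce_to_log_index(self, t_ir, t_red, k, c):
        assert spad_like(t_ir, t_red, SpadLikeParams()) == log_index(t_ir, t_red)
        expected = k * log_index(t_ir, t_red) + c
        assert spad_like(t_ir, t_red, SpadLikeParams(k=k, C=c)) == pytest.approx(
            expected, abs=1e-9, rel=1e-9
        )

    @settings(max_examples=200, derandomize=True)
    @given(
        t_ir=st.floats(1e-6, 1.0),
        t_red=st.floats(1e-6, 1.0),
        factor=st.floats(1e-3, 1.0),
    )
    def test_scale_invariance_of_index(self, t_ir, t_red, factor):
        # Common attenuation (e.g. path length) cancels in the band ratio.
        assert log_index(t_ir * factor, t_red * factor) == pytest.approx(
            log_index(t_ir, t_red), abs=1e-9
        )

    def test_monotonicity_in_each_band(self):
        t = np.linspace(0.05, 0.95, 40)
        m_in_red = [log_index(0.5, tr) for tr in t]
        assert all(np.diff(m_in_red) < 0)  # more red through => less chlorophyll
        m_in_ir = [log_index(ti, 0.5) for ti in t]
        assert all(np.diff(m_in_ir) > 0)


class TestBurstAndAdc:
    def test_average_filter_constant_and_pair(self):
        assert average_filter([4.6] * 10) == pytest.approx(4.6)
        assert average_filter([4.0, 5.0]) == pytest.approx(4.5)

    def test_average_filter_matches_direct_mean(self, rng):
        draws = rng.normal(3.0, 0.01, 10)
        assert average_filter(draws) == pytest.approx(float(np.mean(draws)), abs=1e-15)

    def test_average_filter_rejects_empty(self):
        with pytest.raises(ValueError):
            average_filter([])

    def test_adc_clamps_at_saturation(self):
        det = DetectorConfig(read_noise_sd=0.0)
        assert adc_read(6.2, det) == pytest.approx(5.0)
        assert adc_read(0.0, det) == pytest.approx(0.0)

    def test_adc_quantizes_to_nearest_level(self):
        det = DetectorConfig(read_noise_sd=0.0, adc_bits=10, adc_reference=5.0)
        levels = np.arange(2**10) * det.adc_step  # brute-force level grid
        for v in (0.013, 1.234, 2.4, 3.9999, 4.6):
            expected = levels[np.argmin(np.abs(levels - v))]
            assert adc_read(v, det) == pytest.approx(expected, abs=1e-15)
        # exactly mid-step: either neighbouring level is a valid nearest code
        mid = 511.5 * det.adc_step
        assert adc_read(mid, det) in (511 * det.adc_step, 512 * det.adc_step)

    @settings(max_examples=100, derandomize=True)
    @given(v=st.floats(0.0, 5.0), bits=st.integers(8, 14))
    def test_adc_never_exceeds_saturation_and_stays_on_grid(self, v, bits):
        det = DetectorConfig(read_noise_sd=0.0, adc_bits=bits)
        out = adc_read(v, det, np.random.default_rng(0))
        assert 0.0 <= out <= det.saturation_voltage
        assert abs(out / det.adc_step - round(out / det.adc_step)) < 1e-9


class TestZeroCalibration:
    def test_linear_detector_half_drive(self):
        inst = Instrument(
            detector=DetectorConfig(
                responsivity={Band.RED: 9.2, Band.NIR: 9.2}, read_noise_sd=0.0
            )
        )
        air = zero_calibrate(inst)
        assert inst.led_red.drive_intensity == pytest.approx(0.5, abs=1e-3)
        assert air.v_air_red == pytest.approx(4.6, abs=0.005)
        assert air.persisted

    def test_unreachable_target_raises_with_band(self):
        inst = Instrument(
            detector=DetectorConfig(
                responsivity={Band.RED: 9.2, Band.NIR: 4.0}, read_noise_sd=0.0
            )
        )
        with pytest.raises(CalibrationError) as err:
            zero_calibrate(inst)
        assert err.value.band is Band.NIR

    @settings(max_examples=60, derandomize=True)
    @given(r=st.floats(4.61, 500.0))
    def test_air_voltage_within_tolerance_for_any_responsivity(self, r):
        inst = Instrument(
            detector=DetectorConfig(
                responsivity={Band.RED: r, Band.NIR: r}, read_noise_sd=0.0
            )
        )
        air = zero_calibrate(inst)
        for v in (air.v_air_red, air.v_air_ir):
            assert abs(v - 4.6) <= 0.005

    def test_noise_free_air_scan_reads_target(self, quiet_instrument):
        inst, air = quiet_instrument
        result = scan(OpticalSample(1.0, 1.0), air, inst)
        assert result.v_red == pytest.approx(4.6, abs=0.005)
        assert result.v_ir == pytest.approx(4.6, abs=0.005)


class TestScan:
    def test_air_identity(self, quiet_instrument):
        inst, air = quiet_instrument
        result = scan(OpticalSample(1.0, 1.0), air, inst)
        assert result.t_red == 1.0 and result.t_ir == 1.0
        assert result.cci == 1.0
        assert result.m == 0.0
        assert result.m_display == 0.0

    def test_missing_air_reference(self, quiet_instrument):
        inst, air = quiet_instrument
        from dataclasses import replace

        stale = replace(air, persisted=False)
        with pytest.raises(CalibrationMissingError):
            scan(OpticalSample(0.5, 0.5), stale, inst)

    def test_half_decade_sample(self, quiet_instrument):
        # T_ir/T_red = 10^0.5 by construction.
        inst, air = quiet_instrument
        result = scan(OpticalSample(t_red=0.03, t_nir=0.03 * 10**0.5), air, inst)
        assert result.m_display == pytest.approx(0.50)
        assert result.m == pytest.approx(0.5, abs=0.01)  # quantization only

    def test_opaque_red_sample_is_floored_and_flagged(self, quiet_instrument):
        inst, air = quiet_instrument
        result = scan(OpticalSample(t_red=1e-9, t_nir=0.9), air, inst)
        assert "underflow" in result.flags
        assert math.isfinite(result.m) and result.m > 0

    def test_saturated_sample_is_flagged(self, quiet_instrument):
        inst, air = quiet_instrument
        inst.drift_offset[Band.RED] = 1.0  # pushes the red air path past 5 V
        result = scan(OpticalSample(1.0, 1.0), air, inst)
        assert "saturated" in result.flags
        assert result.v_red <= inst.detector.saturation_voltage

    def test_scale_invariance_end_to_end(self, quiet_instrument):
        inst, air = quiet_instrument
        base = scan(OpticalSample(0.4, 0.6), air, inst)
        scaled = scan(OpticalSample(0.2, 0.3), air, inst)
        # Exact up to ADC quantization of the two voltage pairs.
        assert scaled.m == pytest.approx(base.m, abs=5e-3)

    def test_scan_determinism(self, noisy_instrument):
        inst, air = noisy_instrument
        a = scan(OpticalSample(0.2, 0.5), air, inst, np.random.default_rng(7))
        b = scan(OpticalSample(0.2, 0.5), air, inst, np.random.default_rng(7))
        assert a == b

    def test_registered_conversions_populate_estimates(self, quiet_instrument):
        from virtuchlor import get_preset

        inst, air = quiet_instrument
        inst.conversions["spad"] = get_preset("lemon", "spad")
        inst.conversions["atleaf"] = get_preset("lemon", "atleaf")
        result = scan(OpticalSample(1.0, 1.0), air, inst)
        assert result.spad_est == pytest.approx(13.547)
        assert result.spad_display == pytest.approx(13.5)
        assert result.atleaf_est == pytest.approx(23.577)


class TestConfigValidation:
    def test_led_band_ranges(self):
        with pytest.raises(ValueError):
            LEDSource(Band.RED, peak_wavelength=700.0)
        with pytest.raises(ValueError):
            LEDSource(Band.NIR, peak_wavelength=800.0)

    def test_detector_invariants(self):
        with pytest.raises(ValueError):
            DetectorConfig(calibration_target_voltage=5.5)
        with pytest.raises(ValueError):
            DetectorConfig(adc_bits=6)
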