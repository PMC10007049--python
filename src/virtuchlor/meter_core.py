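"""Measurement chain of a dual-wavelength transmittance chlorophyll meter.

The virtual instrument mirrors the optical/electronic chain of clip-style
chlorophyll meters (SPAD-502, atLeaf CHL Plus, CCM-200 class devices): two
LEDs (red ~650 nm, where chlorophyll absorbs strongly, and near-infrared
~940 nm, a reference band where it does not) shine sequentially through a
sample onto a light-to-voltage detector.  Percentage transmittance per band
is the ratio of the sample voltage to a stored "air" (empty, closed clip)
reference voltage.  The device index is

    M = log10(T_nir / T_red)

the decadic log of the chlorophyll content index CCI = T_nir / T_red.
Larger chlorophyll amounts absorb more red light, lowering T_red and raising
M.  The chain simulated here includes zero (air) calibration by adjusting
LED drive intensity to a target detector voltage, burst averaging of ADC
reads, saturation clamping, quantization and additive read noise.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Band",
    "LEDSource",
    "DetectorConfig",
    "AirReference",
    "SpadLikeParams",
    "ScanResult",
    "Instrument",
    "CalibrationError",
    "CalibrationMissingError",
    "TransmittanceDomainError",
    "percent_transmission",
    "cci",
    "log_index",
    "spad_like",
    "average_filter",
    "adc_read",
    "zero_calibrate",
    "scan",
]


class Band(enum.Enum):
    """Optical band of the measurement: chlorophyll-absorbing red or NIR reference."""

    RED = "red"
    NIR = "nir"


class CalibrationError(RuntimeError):
    """Zero calibration could not reach the target voltage."""

    def __init__(self, band: Band, message: str):
        self.band = band
        super().__init__(message)


class CalibrationMissingError(RuntimeError):
    """A sample scan was requested without a valid air reference."""


class TransmittanceDomainError(ValueError):
    """A transmittance was outside the domain of the log-ratio index."""

    def __init__(self, band: Band, value: float):
        self.band = band
        self.value = value
        super().__init__(
            f"transmittance in band {band.value!r} must be positive, got {value!r}"
        )


@dataclass
class LEDSource:
    """One of the two LED light sources.

    ``drive_intensity`` is the fraction of maximum drive current; the zero
    calibration adjusts it so that the unattenuated (air) detector voltage
    sits just below saturation.
    """

    band: Band
    peak_wavelength: float
    drive_intensity: float = 1.0

    _RANGES = {Band.RED: (640.0, 660.0), Band.NIR: (930.0, 960.0)}

    def __post_init__(self) -> None:
        lo, hi = self._RANGES[self.band]
        if not lo <= self.peak_wavelength <= hi:
            raise ValueError(
                f"{self.band.value} LED peak must lie in [{lo}, {hi}] nm, "
                f"got {self.peak_wavelength}"
            )
        if not 0.0 <= self.drive_intensity <= 1.0:
            raise ValueError("drive_intensity must lie in [0, 1]")


@dataclass
class DetectorConfig:
    """Light-to-voltage detector plus ADC front end.

    ``responsivity`` maps each band to the detector voltage produced by a
    fully driven LED through air (transmittance 1); the red band of this
    detector class is somewhat more sensitive than the NIR band, hence the
    per-band values.  Readings clamp at ``saturation_voltage``; the zero
    calibration targets ``calibration_target_voltage``, deliberately below
    saturation so air never clips.
    """

    saturation_voltage: float = 5.0
    calibration_target_voltage: float = 4.6
    responsivity: Mapping[Band, float] = field(
        default_factory=lambda: {Band.RED: 9.2, Band.NIR: 8.4}
    )
    adc_bits: int = 10
    adc_reference: float = 5.0
    read_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.calibration_target_voltage < self.saturation_voltage:
            raise ValueError(
                "calibration target must lie strictly between 0 and saturation"
            )
        for band in Band:
            if self.responsivity.get(band, 0.0) <= 0.0:
                raise ValueError(f"responsivity must be positive for band {band}")
        if self.adc_bits < 8:
            raise ValueError("adc_bits must be at least 8")
        if self.read_noise_sd < 0.0:
            raise ValueError("read_noise_sd must be non-negative")

    @property
    def adc_step(self) -> float:
        """Voltage width of one ADC code."""
        return self.adc_reference / (2**self.adc_bits - 1)


@dataclass
class AirReference:
    """Persisted air (100 % transmission) voltages from the zero calibration."""

    v_air_red: float
    v_air_ir: float
    timestamp: str = ""
    persisted: bool = False

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        if self.v_air_red <= 0.0 or self.v_air_ir <= 0.0:
            raise ValueError("air reference voltages must be positive")

    def voltage(self, band: Band) -> float:
        return self.v_air_red if band is Band.RED else self.v_air_ir


@dataclass
class SpadLikeParams:
    """Gain/offset of the generic meter law ``k * log10(CCI) + C``.

    Commercial meters keep k and C proprietary; the defaults (k=1, C=0)
    reduce the law to the raw device index M.  Real-meter emulation goes
    through fitted conversion models instead.
    """

    k: float = 1.0
    C: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k) and math.isfinite(self.C)):
            raise ValueError("spad-like parameters must be finite")


@dataclass
class ScanResult:
    """One complete measurement: averaged voltages, transmittances, indices.

    Unrounded values are kept; display forms follow the device convention
    (voltages/transmittances/M to two decimals, converted meter units to one).
    ``flags`` collects anomalies: ``saturated``, ``underflow``, ``over_unity``.
    """

    v_red: float
    v_ir: float
    t_red: float
    t_ir: float
    cci: float
    m: float
    spad_est: Optional[float] = None
    atleaf_est: Optional[float] = None
    flags: frozenset[str] = frozenset()

    @property
    def m_display(self) -> float:
        return round(self.m, 2)

    @property
    def spad_display(self) -> Optional[float]:
        return None if self.spad_est is None else round(self.spad_est, 1)

    @property
    def atleaf_display(self) -> Optional[float]:
        return None if self.atleaf_est is None else round(self.atleaf_est, 1)


@dataclass
class Instrument:
    """The virtual meter: two LEDs, a detector, burst length, unit conversions.

    ``conversions`` maps a target unit name ("spad" or "atleaf") to an object
    with a ``convert(m) -> float`` method (a fitted or preset affine model);
    when registered, each scan also reports the converted estimates.
    ``drift_offset`` is an optional additive detector-voltage offset per band
    (e.g. a temperature-drifted LED), default zero.
    """

    led_red: LEDSource = field(
        default_factory=lambda: LEDSource(Band.RED, peak_wavelength=650.0)
    )
    led_nir: LEDSource = field(
        default_factory=lambda: LEDSource(Band.NIR, peak_wavelength=940.0)
    )
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    burst_length: int = 10
    burst_interval_us: float = 10.0  # metadata only; reads are i.i.d. in simulation
    conversions: dict = field(default_factory=dict)
    drift_offset: dict = field(default_factory=lambda: {Band.RED: 0.0, Band.NIR: 0.0})

    def led(self, band: Band) -> LEDSource:
        return self.led_red if band is Band.RED else self.led_nir


def percent_transmission(v_sample: float, v_air: float) -> float:
    """Fractional transmission: sample voltage over the stored air voltage.

    May slightly exceed 1 for a noisy air-like sample; callers flag that case
    rather than clipping it.
    """
    if v_air <= 0.0:
        raise CalibrationMissingError(
            "air reference voltage must be positive; run zero calibration first"
        )
    if v_sample < 0.0:
        raise ValueError("sample voltage cannot be negative")
    return v_sample / v_air


def cci(t_ir: float, t_red: float) -> float:
    """Chlorophyll content index: NIR over red fractional transmittance."""
    if t_ir <= 0.0:
        raise TransmittanceDomainError(Band.NIR, t_ir)
    if t_red <= 0.0:
        raise TransmittanceDomainError(Band.RED, t_red)
    return t_ir / t_red


def log_index(t_ir: float, t_red: float) -> float:
    """Device output M: decadic log of the NIR/red transmittance ratio."""
    return math.log10(cci(t_ir, t_red))


def spad_like(t_ir: float, t_red: float, params: SpadLikeParams) -> float:
    """Generic meter law ``k * log10(CCI) + C``; defaults reduce to M."""
    return params.k * log_index(t_ir, t_red) + params.C


def average_filter(samples: Sequence[float]) -> float:
    """Burst filter: arithmetic mean of the ADC samples (default burst of 10)."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("average_filter requires a nonempty sample sequence")
    return float(arr.mean())


def adc_read(
    true_voltage: float,
    det: DetectorConfig,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """One ADC sample: add read noise, clamp to [0, saturation], quantize.

    ``rng=None`` gives the noise-free path (used when persisting the air
    reference, so later noise-free scans reproduce it exactly).
    """
    v = true_voltage
    if rng is not None and det.read_noise_sd > 0.0:
        v += rng.normal(0.0, det.read_noise_sd)
    v = min(max(v, 0.0), det.saturation_voltage)
    step = det.adc_step
    v = round(v / step) * step
    return min(v, det.saturation_voltage)


def _air_voltage(instrument: Instrument, band: Band, drive: float) -> float:
    """Noise-free analog detector voltage through air at the given drive."""
    return drive * instrument.detector.responsivity[band] + instrument.drift_offset.get(
        band, 0.0
    )


def zero_calibrate(
    instrument: Instrument,
    tolerance: float = 0.005,
    max_iter: int = 60,
) -> AirReference:
    """Zero the meter: set each LED drive so air reads the calibration target.

    Emulates the manual potentiometer adjustment by bisection on drive
    intensity in [0, 1] until the noise-free air voltage is within
    ``tolerance`` of ``calibration_target_voltage`` (the target sits below
    detector saturation so air never clips).  The achieved voltages are
    passed through the ADC quantizer and persisted as the air reference.
    The instrument's LED drives are updated in place.
    """
    det = instrument.detector
    target = det.calibration_target_voltage
    recorded: dict[Band, float] = {}
    for band in Band:
        if _air_voltage(instrument, band, 1.0) < target:
            raise CalibrationError(
                band,
                f"band {band.value!r}: air voltage at full drive is "
                f"{_air_voltage(instrument, band, 1.0):.3f} V, below the "
                f"calibration target {target} V",
            )
        lo, hi = 0.0, 1.0
        drive = 1.0
        for _ in range(max_iter):
            drive = 0.5 * (lo + hi)
            v = _air_voltage(instrument, band, drive)
            if abs(v - target) < tolerance / 4.0:
                break
            if v < target:
                lo = drive
            else:
                hi = drive
        instrument.led(band).drive_intensity = drive
        recorded[band] = adc_read(_air_voltage(instrument, band, drive), det, rng=None)
    return AirReference(
        v_air_red=recorded[Band.RED], v_air_ir=recorded[Band.NIR], persisted=True
    )


def scan(
    sample,
    air: AirReference,
    instrument: Instrument,
    rng: Optional[np.random.Generator] = None,
) -> ScanResult:
    """One sample measurement: red burst, NIR burst, transmittances, indices.

    ``sample`` is any object with ``t_red`` and ``t_nir`` attributes (band
    transmittances in (0, 1]).  Each LED is "turned on" in turn and the
    detector is sampled ``burst_length`` times; the averaged voltages are
    ratioed against the persisted air reference.  Averaged voltages below one
    ADC step are floored to half a step and flagged ``underflow`` so the log
    ratio stays defined for near-opaque samples.
    """
    if not air.persisted:
        raise CalibrationMissingError("air reference is not persisted; zero the meter")
    det = instrument.detector
    flags: set[str] = set()
    v_avg: dict[Band, float] = {}
    for band, t_band in ((Band.RED, sample.t_red), (Band.NIR, sample.t_nir)):
        true_v = (
            instrument.led(band).drive_intensity * det.responsivity[band] * t_band
            + instrument.drift_offset.get(band, 0.0)
        )
        if true_v >= det.saturation_voltage:
            flags.add("saturated")
        reads = [adc_read(true_v, det, rng) for _ in range(instrument.burst_length)]
        v = average_filter(reads)
        if v < det.adc_step:
            v = det.adc_step / 2.0
            flags.add("underflow")
        v_avg[band] = v
    t_red = percent_transmission(v_avg[Band.RED], air.voltage(Band.RED))
    t_ir = percent_transmission(v_avg[Band.NIR], air.voltage(Band.NIR))
    if t_red > 1.0 or t_ir > 1.0:
        flags.add("over_unity")
    ratio = cci(t_ir, t_red)
    m = math.log10(ratio)
    spad_est = atleaf_est = None
    if "spad" in instrument.conversions:
        spad_est = instrument.conversions["spad"].convert(m)
    if "atleaf" in instrument.conversions:
        atleaf_est = instrument.conversions["atleaf"].convert(m)
    return ScanResult(
        v_red=v_avg[Band.RED],
        v_ir=v_avg[Band.NIR],
        t_red=t_red,
        t_ir=t_ir,
        cci=ratio,
        m=m,
        spad_est=spad_est,
        atleaf_est=atleaf_est,
        flags=frozenset(flags),
    )
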