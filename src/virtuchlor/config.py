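"""TOML configuration files for the virtual instrument and samples."""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Union

from .meter_core import Band, DetectorConfig, Instrument, LEDSource
from .sample_sim import FilterModel, LeafModel, OpticalSample

__all__ = ["load_instrument", "load_sample"]


def load_instrument(path: Union[str, Path]) -> Instrument:
    """Build an Instrument from a TOML file.

    Recognized tables: ``[led.red]`` / ``[led.nir]`` (peak_wavelength,
    drive_intensity), ``[detector]`` (saturation_voltage,
    calibration_target_voltage, responsivity_red, responsivity_nir,
    adc_bits, adc_reference, read_noise_sd), and top-level burst_length.
    Missing keys fall back to the defaults of the virtual device.
    """
    with Path(path).open("rb") as fh:
        cfg = tomllib.load(fh)
    led = cfg.get("led", {})
    red = led.get("red", {})
    nir = led.get("nir", {})
    det = cfg.get("detector", {})
    detector = DetectorConfig(
        saturation_voltage=det.get("saturation_voltage", 5.0),
        calibration_target_voltage=det.get("calibration_target_voltage", 4.6),
        responsivity={
            Band.RED: det.get("responsivity_red", 9.2),
            Band.NIR: det.get("responsivity_nir", 8.4),
        },
        adc_bits=det.get("adc_bits", 10),
        adc_reference=det.get("adc_reference", 5.0),
        read_noise_sd=det.get("read_noise_sd", 0.02),
    )
    return Instrument(
        led_red=LEDSource(
            Band.RED,
            peak_wavelength=red.get("peak_wavelength", 650.0),
            drive_intensity=red.get("drive_intensity", 1.0),
        ),
        led_nir=LEDSource(
            Band.NIR,
            peak_wavelength=nir.get("peak_wavelength", 940.0),
            drive_intensity=nir.get("drive_intensity", 1.0),
        ),
        detector=detector,
        burst_length=cfg.get("burst_length", 10),
    )


def load_sample(path: Union[str, Path]):
    """Load a sample description: a ``[leaf]``, ``[filter]`` or ``[sample]`` table.

    ``[leaf]`` takes the LeafModel fields; ``[filter]`` the FilterModel
    fields; ``[sample]`` takes raw ``t_red``/``t_nir`` transmittances.
    """
    with Path(path).open("rb") as fh:
        cfg = tomllib.load(fh)
    if "leaf" in cfg:
        return LeafModel(**cfg["leaf"])
    if "filter" in cfg:
        return FilterModel(**cfg["filter"])
    if "sample" in cfg:
        return OpticalSample(**cfg["sample"])
    raise ValueError("sample file must contain a [leaf], [filter] or [sample] table")
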