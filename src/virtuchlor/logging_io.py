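"""Measurement-record log format and session operations.

The device stores each measurement on its SD card as one record: the
running measurement number, a timestamp, the two air-reference voltages,
the two band transmittances, the device index M (two-decimal display
form), optional converted SPAD/atLeaf estimates (one decimal), optional
GPS coordinates and a row checksum.  This module defines that record as a
CSV dialect (comma separator, UTF-8, LF endings, empty string for absent
fields, ISO-8601 timestamps) and round-trips it; and it provides the
session operations of the device firmware: append, reject the most recent
measurement, and average stored values.

The checksum is the CRC-32 of the comma-joined preceding fields, as eight
lowercase hex digits — a documented artifact convention for row integrity,
sufficient to detect any single-character corruption.
"""

from __future__ import annotations

import csv
import hashlib
import zlib
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import List, Optional, Tuple, Union

from .meter_core import AirReference, Instrument, ScanResult

__all__ = [
    "MeasurementRecord",
    "Session",
    "ChecksumError",
    "COLUMNS",
    "record_from_scan",
    "write_records",
    "read_records",
    "append_record",
    "reject_last",
    "session_average",
]

COLUMNS = (
    "measurement_number",
    "timestamp",
    "V_red_air",
    "V_ir_air",
    "T_red",
    "T_ir",
    "M",
    "spad_est",
    "atleaf_est",
    "latitude",
    "longitude",
    "checksum",
)


class ChecksumError(ValueError):
    """A log row failed checksum validation."""

    def __init__(self, row_number: int, line: str):
        self.row_number = row_number
        super().__init__(f"checksum mismatch at data row {row_number}: {line!r}")


def _fmt(value: Optional[float], decimals: int) -> str:
    return "" if value is None else f"{value:.{decimals}f}"


@dataclass(frozen=True)
class MeasurementRecord:
    """One stored measurement in display precision.

    Stored values carry the device's display rounding (two decimals for
    voltages, transmittances and M; one for converted estimates; six for
    coordinates), applied on construction so that a write/read round trip
    is an identity.
    """

    measurement_number: int
    timestamp: str
    v_red_air: float
    v_ir_air: float
    t_red: float
    t_ir: float
    m: float
    spad_est: Optional[float] = None
    atleaf_est: Optional[float] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None

    def __post_init__(self) -> None:
        if self.measurement_number < 1:
            raise ValueError("measurement_number must be a positive integer")
        rounded = {
            "v_red_air": round(self.v_red_air, 2),
            "v_ir_air": round(self.v_ir_air, 2),
            "t_red": round(self.t_red, 2),
            "t_ir": round(self.t_ir, 2),
            "m": round(self.m, 2),
            "spad_est": None if self.spad_est is None else round(self.spad_est, 1),
            "atleaf_est": None
            if self.atleaf_est is None
            else round(self.atleaf_est, 1),
            "latitude": None if self.latitude is None else round(self.latitude, 6),
            "longitude": None if self.longitude is None else round(self.longitude, 6),
        }
        for name, value in rounded.items():
            object.__setattr__(self, name, value)

    def fields(self) -> List[str]:
        """The record's serialized fields, checksum excluded."""
        return [
            str(self.measurement_number),
            self.timestamp,
            _fmt(self.v_red_air, 2),
            _fmt(self.v_ir_air, 2),
            _fmt(self.t_red, 2),
            _fmt(self.t_ir, 2),
            _fmt(self.m, 2),
            _fmt(self.spad_est, 1),
            _fmt(self.atleaf_est, 1),
            _fmt(self.latitude, 6),
            _fmt(self.longitude, 6),
        ]

    def checksum(self) -> str:
        return f"{zlib.crc32(','.join(self.fields()).encode('utf-8')):08x}"


def record_from_scan(
    number: int,
    timestamp: str,
    result: ScanResult,
    air: AirReference,
    latitude: Optional[float] = None,
    longitude: Optional[float] = None,
) -> MeasurementRecord:
    """Build a log record from a scan result and the active air reference."""
    return MeasurementRecord(
        measurement_number=number,
        timestamp=timestamp,
        v_red_air=air.v_air_red,
        v_ir_air=air.v_air_ir,
        t_red=result.t_red,
        t_ir=result.t_ir,
        m=result.m,
        spad_est=result.spad_est,
        atleaf_est=result.atleaf_est,
        latitude=latitude,
        longitude=longitude,
    )


def write_records(
    records: List[MeasurementRecord], path: Union[str, Path]
) -> Path:
    """Write records as CSV (header + one line each, checksum last column)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COLUMNS)
        for rec in records:
            writer.writerow(rec.fields() + [rec.checksum()])
    return path


def _parse_optional(text: str) -> Optional[float]:
    return None if text == "" else float(text)


def read_records(
    path: Union[str, Path], strict: bool = True
) -> Tuple[List[MeasurementRecord], List[int]]:
    """Read and checksum-validate a log file.

    Returns ``(records, flagged_rows)``.  In strict mode any malformed row
    or checksum mismatch raises; in lenient mode the offending 1-based data
    row numbers are returned in ``flagged_rows`` and the row is skipped.
    """
    path = Path(path)
    records: List[MeasurementRecord] = []
    flagged: List[int] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != list(COLUMNS):
            raise ValueError(f"unrecognized log header: {header}")
        for row_number, row in enumerate(reader, start=1):
            line = ",".join(row)
            try:
                if len(row) != len(COLUMNS):
                    raise ValueError(f"row {row_number}: expected "
                                     f"{len(COLUMNS)} fields, got {len(row)}")
                *fields, checksum = row
                expected = f"{zlib.crc32(','.join(fields).encode('utf-8')):08x}"
                if checksum != expected:
                    raise ChecksumError(row_number, line)
                records.append(
                    MeasurementRecord(
                        measurement_number=int(fields[0]),
                        timestamp=fields[1],
                        v_red_air=float(fields[2]),
                        v_ir_air=float(fields[3]),
                        t_red=float(fields[4]),
                        t_ir=float(fields[5]),
                        m=float(fields[6]),
                        spad_est=_parse_optional(fields[7]),
                        atleaf_est=_parse_optional(fields[8]),
                        latitude=_parse_optional(fields[9]),
                        longitude=_parse_optional(fields[10]),
                    )
                )
            except (ValueError, IndexError) as exc:
                if strict:
                    raise
                flagged.append(row_number)
    return records, flagged


def config_fingerprint(instrument: Instrument) -> str:
    """Stable short hash of the instrument configuration."""
    det = instrument.detector
    parts = [
        f"{instrument.led_red.peak_wavelength}",
        f"{instrument.led_nir.peak_wavelength}",
        f"{det.saturation_voltage}",
        f"{det.calibration_target_voltage}",
        *(f"{band.value}={det.responsivity[band]}" for band in det.responsivity),
        f"{det.adc_bits}",
        f"{det.adc_reference}",
        f"{det.read_noise_sd}",
        f"{instrument.burst_length}",
    ]
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:12]


@dataclass
class Session:
    """An in-memory measurement session: air reference first, then records."""

    air: AirReference
    config_fingerprint: str = ""
    records: List[MeasurementRecord] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.air.persisted:
            raise ValueError("a session requires a persisted air reference")


def append_record(session: Session, record: MeasurementRecord) -> Session:
    """Append a record; numbering must continue strictly increasing."""
    if session.records and record.measurement_number <= session.records[-1].measurement_number:
        raise ValueError("measurement numbers must be strictly increasing")
    session.records.append(record)
    return session


def reject_last(session: Session) -> Session:
    """Drop the most recent measurement; earlier numbering is untouched."""
    if not session.records:
        raise ValueError("cannot reject from an empty session")
    session.records.pop()
    return session


def session_average(session: Session, field: str = "m") -> Tuple[float, int]:
    """Mean of a stored field ('m', 'spad_est' or 'atleaf_est') over records.

    Absent values (unregistered conversions) are skipped; returns the mean
    over present values and how many records contributed.
    """
    if field not in ("m", "spad_est", "atleaf_est"):
        raise ValueError("field must be one of 'm', 'spad_est', 'atleaf_est'")
    values = [
        getattr(rec, field) for rec in session.records if getattr(rec, field) is not None
    ]
    if not values:
        raise ValueError(f"no records with field {field!r} present")
    return sum(values) / len(values), len(values)
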