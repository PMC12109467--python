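"""Printed study cohort and file I/O.

Houses the 11-recording HVAD cohort (clinical/pump metadata and the
normalized harmonic power feature table) as compiled-in fixtures, plus
readers/writers for accelerometer time series (WAV or single-column CSV)
and harmonic-power feature tables (CSV).

Outcome convention: ``YES`` (thrombosis diagnosed) is the positive class
throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "ClinicalRecord",
    "HarmonicProfile",
    "Recording",
    "HARMONIC_COLUMNS",
    "load_embedded_cohort",
    "read_timeseries",
    "write_feature_table",
    "read_feature_table",
]

log = logging.getLogger(__name__)

#: Column names of the 12 harmonic power features, fundamental first.
HARMONIC_COLUMNS: tuple[str, ...] = ("P_FF",) + tuple(f"P_{n}H" for n in range(2, 13))

OUTCOMES = ("YES", "NO")


class SchemaError(ValueError):
    """A tabular input does not match the expected column schema."""


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical and pump-operational metadata for one recording.

    ``pump_fundamental`` is the pump rotation rate in Hz (rpm / 60); the
    acoustic fundamental of the recording sits at this frequency.
    """

    patient_id: str
    ldh: float  # lactate dehydrogenase, U/L
    pump_speed: float  # rpm
    pump_fundamental: float  # Hz
    pump_power: float  # W
    hvad_age: int  # days since implant
    outcome: str  # thrombosis diagnosis, YES or NO

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be YES or NO, got {self.outcome!r}")


@dataclass(frozen=True)
class HarmonicProfile:
    """Normalized harmonic power signature of one recording.

    ``power_db`` holds (P_FF, P_2H, ..., P_12H) in dB relative to the
    FF-12H total, i.e. the linearized powers sum to 1 (0 dB). ``outcome``
    may be None for profiles freshly extracted from a recording.
    """

    patient_id: str
    power_db: tuple[float, ...]
    outcome: str | None = None

    def __post_init__(self) -> None:
        if len(self.power_db) != 12:
            raise ValueError(f"expected 12 harmonic powers, got {len(self.power_db)}")
        if self.outcome is not None and self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be YES, NO or None, got {self.outcome!r}")

    def linear_powers(self) -> np.ndarray:
        """Harmonic powers on the linear scale (fractions of the total)."""
        return 10.0 ** (np.asarray(self.power_db) / 10.0)


@dataclass(frozen=True)
class Recording:
    """A sampled acceleration time series."""

    patient_id: str
    samples: np.ndarray = field(repr=False)
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sampling_rate


# The printed cohort. Clinical table: patient, LDH (U/L), pump speed (rpm),
# pump fundamental (Hz), pump power (W), device age (days), outcome.
_CLINICAL_ROWS = (
    ("HW-A", 190, 2560, 42.67, 3.1, 1853, "NO"),
    ("HW-B", 348, 2600, 43.33, 3.6, 1597, "NO"),
    ("HW-C", 213, 2620, 43.67, 3.9, 959, "NO"),
    ("HW-D1", 4458, 2540, 42.33, 7.0, 2258, "YES"),
    ("HW-D2", 3585, 2540, 42.33, 12.2, 2262, "YES"),
    ("HW-E", 275, 2660, 44.33, 3.9, 1472, "NO"),
    ("HW-F1", 292, 2700, 45.0, 4.7, 818, "NO"),
    ("HW-F2", 3330, 2800, 46.67, 6.2, 1253, "YES"),
    ("HW-G", 253, 2600, 43.33, 3.7, 1444, "NO"),
    ("HW-H", 154, 2700, 45.0, 4.1, 2034, "NO"),
    ("HW-I", 311, 2800, 46.67, 4.8, 3461, "NO"),
)

# Feature table: normalized harmonic powers P_FF..P_12H in dB (sum of
# linearized powers = 0 dB) plus the thrombosis outcome.
_PROFILE_ROWS = (
    ("HW-A", (-0.0709, -24.5376, -42.7136, -19.0600, -46.5642, -47.9261,
              -50.3521, -40.3536, -48.5813, -49.5637, -49.7301, -46.0885), "NO"),
    ("HW-B", (-3.5042, -8.7993, -22.1829, -3.8459, -29.3450, -34.5989,
              -35.1714, -33.5871, -36.9125, -37.9513, -34.1700, -34.3805), "NO"),
    ("HW-C", (-0.0157, -28.4070, -36.9364, -27.5495, -43.5894, -46.8234,
              -46.3518, -41.9392, -54.6824, -53.3172, -54.4150, -44.9496), "NO"),
    ("HW-D1", (-1.4809, -10.6403, -23.9485, -7.2912, -27.4535, -26.5844,
               -27.9201, -27.7818, -30.2167, -30.1508, -28.6569, -28.2910), "YES"),
    ("HW-D2", (-0.2563, -13.8401, -21.2248, -22.7990, -32.9389, -33.3901,
               -33.4354, -34.9352, -34.0925, -34.6498, -34.4029, -34.1315), "YES"),
    ("HW-E", (-0.1489, -28.2704, -31.7187, -15.5442, -32.5102, -33.0632,
              -33.5801, -34.0536, -33.0876, -34.0219, -32.7320, -34.8687), "NO"),
    ("HW-F1", (-0.0551, -24.2720, -37.3658, -20.9277, -39.5058, -40.5999,
               -40.6656, -40.6629, -41.5667, -42.2361, -42.7583, -42.0199), "NO"),
    ("HW-F2", (-0.2059, -14.6536, -27.4858, -20.0872, -41.3635, -43.3848,
               -43.0292, -37.5080, -45.6187, -45.9965, -45.1245, -45.2195), "YES"),
    ("HW-G", (-4.1746, -13.2433, -22.2679, -2.6211, -22.8487, -26.5414,
              -32.6231, -20.9933, -39.5206, -41.2349, -41.5568, -29.1602), "NO"),
    ("HW-H", (-0.0583, -30.1282, -36.7897, -19.3974, -39.3128, -40.2933,
              -41.0277, -39.5763, -42.1642, -41.5989, -42.2536, -40.8596), "NO"),
    ("HW-I", (-9.1241, -23.4190, -27.7626, -0.6080, -32.2090, -35.7505,
              -40.1552, -30.3619, -42.9335, -44.7409, -46.1173, -41.1794), "NO"),
)


def load_embedded_cohort() -> tuple[list[ClinicalRecord], list[HarmonicProfile]]:
    """Return the 11-recording study cohort (clinical table, feature table).

    Both lists carry identical patient_id sets; 3 of the 11 recordings have
    a thrombosis outcome of YES.
    """
    clinical = [ClinicalRecord(*row) for row in _CLINICAL_ROWS]
    profiles = [HarmonicProfile(pid, powers, outcome)
                for pid, powers, outcome in _PROFILE_ROWS]
    return clinical, profiles


def read_timeseries(path: str | Path,
                    sampling_rate_override: float | None = None,
                    patient_id: str | None = None) -> Recording:
    """Read an acceleration time series from a WAV or single-column CSV file.

    WAV files provide their own sampling rate (an override, if given, wins
    and is logged); CSV files carry no rate and require
    ``sampling_rate_override``. The sample mean is removed — PSD features
    are insensitive to the DC offset of an uncalibrated accelerometer chain
    — and no other detrending or resampling is applied.
    """
    path = Path(path)
    name = patient_id if patient_id is not None else path.stem
    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            data = data[:, 0]
        if sampling_rate_override is not None and sampling_rate_override != rate:
            log.info("overriding WAV header rate %s Hz with %s Hz", rate,
                     sampling_rate_override)
            rate = sampling_rate_override
        samples = np.asarray(data, dtype=float)
    else:
        if sampling_rate_override is None:
            raise ValueError(
                f"{path}: CSV time series carries no sampling rate; "
                "pass sampling_rate_override")
        rate = sampling_rate_override
        values = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                text = line.strip()
                if not text:
                    continue
                try:
                    values.append(float(text))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric sample {text!r}") from None
        samples = np.asarray(values, dtype=float)
    if samples.size:
        mean = samples.mean()
        samples = samples - mean
        log.debug("removed mean %.6g from %s (%d samples)", mean, path, samples.size)
    return Recording(patient_id=name, samples=samples, sampling_rate=float(rate))


def write_timeseries(rec: Recording, path: str | Path) -> Path:
    """Write a Recording to WAV (float32) or single-column CSV by extension."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(rec.sampling_rate)),
                      rec.samples.astype(np.float32))
    else:
        np.savetxt(path, rec.samples, fmt="%.9g")
    return path


_FEATURE_HEADER = ("patient_id",) + HARMONIC_COLUMNS + ("outcome",)


def write_feature_table(profiles: Sequence[HarmonicProfile],
                        path: str | Path) -> Path:
    """Write harmonic profiles as a CSV feature table (4 dB decimals).

    Schema: ``patient_id,P_FF,P_2H,...,P_12H,outcome``; comma-separated,
    UTF-8, '.' decimal.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    ids = [p.patient_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient_id(s): {dupes}")
    rows = [
        {"patient_id": p.patient_id,
         **{c: f"{v:.4f}" for c, v in zip(HARMONIC_COLUMNS, p.power_db)},
         "outcome": p.outcome if p.outcome is not None else ""}
        for p in profiles
    ]
    frame = pd.DataFrame(rows, columns=list(_FEATURE_HEADER))
    frame.to_csv(path, index=False, encoding="utf-8")
    return Path(path)


def read_feature_table(path: str | Path) -> list[HarmonicProfile]:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    frame = pd.read_csv(path, dtype={"patient_id": str, "outcome": str})
    expected = set(_FEATURE_HEADER)
    got = set(frame.columns)
    missing = sorted(expected - got)
    extra = sorted(got - expected)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")
    ids = frame["patient_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate patient_id(s): {dupes}")
    profiles = []
    for _, row in frame.iterrows():
        outcome = row["outcome"]
        if pd.isna(outcome) or outcome == "":
            outcome = None
        profiles.append(HarmonicProfile(
            patient_id=row["patient_id"],
            power_db=tuple(float(row[c]) for c in HARMONIC_COLUMNS),
            outcome=outcome))
    return profiles
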