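"""Ionometric dose determination and the GUM uncertainty budget.

Implements the calibration-based dose equation

    Dw,Q = M_Q * N_D,w,Qo * kQ,Qo

where M_Q is the electrometer reading corrected for influence quantities
(air density, polarity, ion recombination, electrometer), N_D,w,Qo the
dose-to-water calibration coefficient in the Co-60 reference quality, and
kQ,Qo the beam-quality correction interpolated at the measurement
distance.  Uncertainties combine in quadrature per the GUM.

Reference conditions default to T0 = 20 C, P0 = 101.325 kPa (the TRS-398
convention).  Ion recombination uses the two-voltage method in its
continuous-radiation (near-saturation) form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

T0_CELSIUS = 20.0
P0_KPA = 101.325


@dataclass
class MeasurementRecord:
    """One timed charge collection with its influence-quantity readings."""

    raw_charge_nc: float
    collection_time_min: float
    temperature_c: float
    pressure_kpa: float
    polarity_readings: tuple[float, float]  # (M+, M-) nC
    two_voltage_readings: tuple[float, float]  # (M_V1, M_V2) nC
    voltage_ratio: float  # V1 / V2 > 1
    calibration_coefficient: float  # N_D,w,Qo [Gy/nC]
    position_cm: tuple[float, float]  # (y, z) in the source frame
    electrometer_correction: float = 1.0

    def __post_init__(self):
        if self.collection_time_min <= 0:
            raise ValueError("collection time must be positive")
        if not (-50.0 < self.temperature_c < 60.0) or not (50.0 < self.pressure_kpa < 150.0):
            raise ValueError("unphysical environmental conditions")


@dataclass
class InfluenceCorrections:
    k_tp: float
    k_pol: float
    k_ion: float
    k_elec: float

    def __post_init__(self):
        for name in ("k_tp", "k_pol", "k_ion", "k_elec"):
            v = getattr(self, name)
            if not 0.9 < v < 1.1:
                raise ValueError(f"{name} = {v:.4f} outside the sane range (0.9, 1.1)")

    @property
    def product(self) -> float:
        return self.k_tp * self.k_pol * self.k_ion * self.k_elec


def corrected_reading(
    record: MeasurementRecord,
    t0_c: float = T0_CELSIUS,
    p0_kpa: float = P0_KPA,
) -> tuple[float, InfluenceCorrections]:
    """Influence-corrected reading M_Q [nC] and the individual factors.

    k_TP scales the collected charge to reference air density, k_pol
    averages the two polarities, k_ion applies the continuous-beam
    two-voltage recombination correction, and k_elec is the electrometer
    calibration factor carried on the record.
    """
    if record.raw_charge_nc == 0:
        raise ValueError("zero electrometer reading")
    k_tp = (273.15 + record.temperature_c) / (273.15 + t0_c) * (p0_kpa / record.pressure_kpa)
    m_plus, m_minus = record.polarity_readings
    if m_plus == 0 or m_minus == 0:
        raise ValueError("zero polarity reading")
    k_pol = (abs(m_plus) + abs(m_minus)) / (2.0 * abs(record.raw_charge_nc))
    m1, m2 = record.two_voltage_readings
    v = record.voltage_ratio
    if v <= 1.0:
        raise ValueError("two-voltage method requires V1/V2 > 1")
    if m1 == 0 or m2 == 0:
        raise ValueError("zero two-voltage reading")
    k_ion = (v**2 - 1.0) / (v**2 - m1 / m2)
    corr = InfluenceCorrections(k_tp=k_tp, k_pol=k_pol, k_ion=k_ion, k_elec=record.electrometer_correction)
    return record.raw_charge_nc * corr.product, corr


@dataclass
class KqLookup:
    """Per-detector table of (distance cm, kQ,Qo, stderr) with linear
    interpolation between tabulated distances."""

    detector: str
    distances_cm: np.ndarray
    kq: np.ndarray
    stderr: np.ndarray | None = None

    def __post_init__(self):
        self.distances_cm = np.asarray(self.distances_cm, dtype=float)
        self.kq = np.asarray(self.kq, dtype=float)
        if np.any(np.diff(self.distances_cm) <= 0):
            raise ValueError("distances must be strictly ascending")
        if np.any(self.kq <= 0):
            raise ValueError("kq values must be positive")

    def __call__(self, distance_cm: float) -> float:
        d = self.distances_cm
        if distance_cm < d[0] or distance_cm > d[-1]:
            raise ValueError(f"distance {distance_cm} cm outside lookup range [{d[0]}, {d[-1]}]")
        return float(np.interp(distance_cm, d, self.kq))


IDENTITY_KQ = KqLookup("identity", np.array([0.1, 100.0]), np.array([1.0, 1.0]))


def dose_from_reading(m_q: float, n_dw: float, kq: float | KqLookup = 1.0, distance_cm: float | None = None) -> float:
    """Dose to water [Gy] = M_Q * N_D,w,Qo * kQ,Qo.

    ``kq`` may be a number or a :class:`KqLookup` (then ``distance_cm``
    selects the interpolated value)."""
    if n_dw <= 0:
        raise ValueError("calibration coefficient must be positive")
    if isinstance(kq, KqLookup):
        if distance_cm is None:
            raise ValueError("distance required for a kq lookup")
        kq = kq(distance_cm)
    return m_q * n_dw * kq


# ---------------------------------------------------------------------------
# Uncertainty budget
# ---------------------------------------------------------------------------


@dataclass
class UncertaintyBudget:
    """GUM-style budget: named components [%] of type A or B."""

    components: tuple[tuple[str, str, float], ...]  # (name, "A"|"B", percent)
    coverage_factor: float = 1.0

    def __post_init__(self):
        for name, kind, pct in self.components:
            if kind not in ("A", "B"):
                raise ValueError(f"component {name!r}: type must be 'A' or 'B'")
            if pct < 0:
                raise ValueError(f"component {name!r}: negative uncertainty")

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.components, columns=["component", "type", "percent"])
        return df


#: The measurement budget at the 1 cm reference away-distance for the
#: small-cavity chamber used in the water-phantom protocol.
REFERENCE_BUDGET = UncertaintyBudget(
    components=(
        ("kQ,Qo statistical", "A", 0.21),
        ("kQ,Qo systematic", "B", 0.78),
        ("N_D,w calibration", "B", 0.55),
        ("influence corrections", "B", 0.10),
        ("signal measurement", "A", 0.01),
        ("source-detector positioning", "B", 1.2),
    )
)


def combine_uncertainty(budget: UncertaintyBudget) -> float:
    """Combined uncertainty [%] at the budget's coverage factor
    (root sum of squares of all components, times k)."""
    if not budget.components:
        raise ValueError("empty budget")
    rss = math.sqrt(sum(p**2 for _, _, p in budget.components))
    return budget.coverage_factor * rss


# ---------------------------------------------------------------------------
# Chamber alignment from scan profiles
# ---------------------------------------------------------------------------


def align_from_scan(profile) -> float:
    """Symmetry center of a scanned signal profile via a parabolic fit.

    ``profile`` is a sequence of (position, signal) pairs spanning an
    interior maximum; returns the fitted peak position.  Raises on
    profiles without an interior maximum (monotone or flat).
    """
    arr = np.asarray(profile, dtype=float)
    if arr.ndim != 2 or len(arr) < 5:
        raise ValueError("need at least 5 scan points")
    x, s = arr[:, 0], arr[:, 1]
    order = np.argsort(x)
    x, s = x[order], s[order]
    i = int(np.argmax(s))
    if i == 0 or i == len(s) - 1:
        raise ValueError("no interior maximum in scan profile")
    # a window of up to 9 points centered on the peak: wide enough to
    # average noise, narrow enough that a symmetric peak stays parabolic
    lo, hi = max(0, i - 4), min(len(s), i + 5)
    coeffs = np.polyfit(x[lo:hi], s[lo:hi], 2)
    if coeffs[0] >= 0 or abs(coeffs[0]) < 1e-12 * max(1.0, abs(s[i])):
        raise ValueError("profile is flat around the maximum")
    return float(-coeffs[1] / (2.0 * coeffs[0]))


# ---------------------------------------------------------------------------
# Record I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "raw_charge_nc",
    "collection_time_min",
    "temperature_c",
    "pressure_kpa",
    "m_plus_nc",
    "m_minus_nc",
    "m_v1_nc",
    "m_v2_nc",
    "voltage_ratio",
    "calibration_gy_per_nc",
    "y_cm",
    "z_cm",
    "electrometer_correction",
]


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            dict(
                zip(
                    _CSV_COLUMNS,
                    [
                        r.raw_charge_nc,
                        r.collection_time_min,
                        r.temperature_c,
                        r.pressure_kpa,
                        r.polarity_readings[0],
                        r.polarity_readings[1],
                        r.two_voltage_readings[0],
                        r.two_voltage_readings[1],
                        r.voltage_ratio,
                        r.calibration_coefficient,
                        r.position_cm[0],
                        r.position_cm[1],
                        r.electrometer_correction,
                    ],
                )
            )
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[MeasurementRecord]:
    out = []
    for _, row in df.iterrows():
        out.append(
            MeasurementRecord(
                raw_charge_nc=float(row["raw_charge_nc"]),
                collection_time_min=float(row["collection_time_min"]),
                temperature_c=float(row["temperature_c"]),
                pressure_kpa=float(row["pressure_kpa"]),
                polarity_readings=(float(row["m_plus_nc"]), float(row["m_minus_nc"])),
                two_voltage_readings=(float(row["m_v1_nc"]), float(row["m_v2_nc"])),
                voltage_ratio=float(row["voltage_ratio"]),
                calibration_coefficient=float(row["calibration_gy_per_nc"]),
                position_cm=(float(row["y_cm"]), float(row["z_cm"])),
                electrometer_correction=float(row.get("electrometer_correction", 1.0)),
            )
        )
    return out


def measured_dose_rate(record: MeasurementRecord, kq: float | KqLookup = 1.0) -> float:
    """Dose rate [Gy/min] from one record via the full correction chain."""
    m_q, _ = corrected_reading(record)
    distance = math.hypot(*record.position_cm)
    dose = dose_from_reading(m_q, record.calibration_coefficient, kq, distance_cm=distance)
    return dose / record.collection_time_min
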