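"""Synthetic inputs: electrometer readings, toy detectors, reduced runs.

No measurement data ship with the package; this module fabricates
schema-valid inputs for every pipeline stage.  ``generate_readings``
emulates the water-phantom protocol: repeated timed charge collections
around a source of known air-kerma strength, with multiplicative reading
noise and re-sampled Gaussian positioning offsets, plus self-consistent
polarity / two-voltage / environmental fields so that the full correction
chain recovers the generating truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import DetectorModel
from .protocol import IDENTITY_KQ, KqLookup, MeasurementRecord
from .tg43 import Tg43Params, tg43_dose_rate
from .transport import TransportConfig

# Self-consistent influence-quantity truths used by the generator
_TRUE_K_ION = 1.003
_TRUE_POLARITY_ASYMMETRY = 0.002
_VOLTAGE_RATIO = 4.0


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground truth and noise structure of a simulated measurement session.

    Defaults mirror the documented protocol conditions: four repeated
    5-minute collections per point, and a per-reading positioning spread
    (0.12 mm) whose standard error over four repeats reproduces the 1.2%
    dose scatter quoted at the 1 cm reference distance.
    """

    true_sk: float = 21954.50  # U
    true_lambda: float = 1.109  # cGy / (h U)
    reading_noise: float = 0.001  # relative SD per reading
    positioning_noise_mm: float = 0.12  # SD per reading, each axis
    n_repeats: int = 4
    seed: int = 0
    collection_time_min: float = 5.0
    calibration_gy_per_nc: float = 1.0

    def __post_init__(self):
        if self.reading_noise < 0 or self.positioning_noise_mm < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.n_repeats < 1:
            raise ValueError("need at least one repeat")


def generate_readings(
    scenario: SyntheticScenario,
    positions: list[tuple[float, float]],
    kq: KqLookup | float = IDENTITY_KQ,
) -> list[MeasurementRecord]:
    """Simulate charge-collection records at (y, z) positions [cm].

    The true dose rate comes from the TG-43 field of the scenario source;
    each repeat perturbs the detector position isotropically in (y, z)
    and the reading multiplicatively, then back-computes the raw charge
    so that the correction chain (k_TP, k_pol, k_ion) is self-consistent.
    Records carry the *nominal* position, as in a real session.
    """
    rng = np.random.default_rng(scenario.seed)
    params = Tg43Params(sk=scenario.true_sk, dose_rate_constant=scenario.true_lambda)
    records: list[MeasurementRecord] = []
    for y, z in positions:
        nominal_r = math.hypot(y, z)
        if nominal_r <= 0:
            raise ValueError("measurement position cannot coincide with the source")
        for _ in range(scenario.n_repeats):
            dy, dz = rng.normal(0.0, scenario.positioning_noise_mm / 10.0, size=2)
            true_r = math.hypot(y + dy, z + dz)
            rate = tg43_dose_rate(params, true_r)  # Gy/min
            dose = rate * scenario.collection_time_min
            dose *= 1.0 + rng.normal(0.0, scenario.reading_noise)

            kq_val = kq(nominal_r) if isinstance(kq, KqLookup) else float(kq)
            m_q = dose / (scenario.calibration_gy_per_nc * kq_val)

            temperature = rng.normal(20.5, 0.5)
            pressure = rng.normal(100.8, 0.4)
            k_tp = (273.15 + temperature) / 293.15 * (101.325 / pressure)
            delta = _TRUE_POLARITY_ASYMMETRY
            k_pol = 1.0 / (1.0 + delta)
            raw = m_q / (k_tp * k_pol * _TRUE_K_ION)
            v2 = _VOLTAGE_RATIO**2
            m2 = raw / (v2 - (v2 - 1.0) / _TRUE_K_ION)
            records.append(
                MeasurementRecord(
                    raw_charge_nc=raw,
                    collection_time_min=scenario.collection_time_min,
                    temperature_c=temperature,
                    pressure_kpa=pressure,
                    polarity_readings=(raw, -raw * (2.0 * k_pol - 1.0)),
                    two_voltage_readings=(raw, m2),
                    voltage_ratio=_VOLTAGE_RATIO,
                    calibration_coefficient=scenario.calibration_gy_per_nc,
                    position_cm=(y, z),
                )
            )
    return records


def toy_detector(kind: str) -> DetectorModel:
    """Fixture detectors for invariant tests.

    * ``water_mimic``: every component water, voxel-sized cavity — all
      dose ratios and kq are 1 up to statistics.
    * ``big_cylinder``: the Farmer-sized A12 cavity filled with water and
      a water wall — isolates pure volume averaging.
    * ``high_z_electrode``: small chamber with a silver electrode — the
      electron-transport overresponse fixture.
    """
    if kind == "water_mimic":
        return DetectorModel(
            name="water_mimic",
            kind="cylinder",
            cavity_diameter=2.0,
            cavity_length=2.0,
            gas="water",
            wall=(("water", 0.25),),
            electrode=None,
            nominal_volume_mm3=math.pi * 1.0**2 * 2.0,
        )
    if kind == "big_cylinder":
        return DetectorModel(
            name="big_cylinder",
            kind="cylinder",
            cavity_diameter=6.1,
            cavity_length=25.8,
            gas="water",
            wall=(("water", 0.25),),
            electrode=None,
            nominal_volume_mm3=math.pi * 3.05**2 * 25.8,
        )
    if kind == "high_z_electrode":
        return DetectorModel(
            name="high_z_electrode",
            kind="cylinder",
            cavity_diameter=2.0,
            cavity_length=3.6,
            gas="air",
            wall=(("c552", 0.5),),
            electrode=("silver", 0.6),
            nominal_volume_mm3=10.0,
        )
    raise ValueError(f"unknown toy detector kind {kind!r}")


def reduced_config(config: TransportConfig, scale: float) -> TransportConfig:
    """Scale the number of histories of a run configuration.

    Batches are preserved, so the standard error is expected to grow as
    ``1/sqrt(scale)``.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    n = int(round(config.n_histories * scale))
    if n < config.n_batches:
        raise ValueError("scaled histories fall below the batch count")
    return replace(config, n_histories=n)
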