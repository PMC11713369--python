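"""Point-source TG-43 dose-rate engine and measured-vs-calculated tables.

The 1D point-source formalism parametrizes the water dose rate around a
brachytherapy source as

    Ddot(r) = Sk * Lambda * (1 cm / r)^2 * g(r) * phi_an(r)

with Sk the air-kerma strength (1 U = 1 uGy m^2/h = 1 cGy cm^2/h),
Lambda the dose-rate constant [cGy h^-1 U^-1], g the radial dose function
normalized to g(1 cm) = 1, and phi_an the 1D anisotropy factor (default
1).  Dose rates are returned in Gy/min, the unit used for HDR
measurement reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CGY_PER_H_TO_GY_PER_MIN


@dataclass
class Tg43Params:
    """Source strength and consensus parameters of the 1D formalism."""

    sk: float  # air-kerma strength [U]
    dose_rate_constant: float  # Lambda [cGy / (h U)]
    radial_dose: tuple[tuple[float, float], ...] = ()  # (r cm, g(r)); empty -> g == 1
    anisotropy: tuple[tuple[float, float], ...] = ()  # (r cm, phi_an); empty -> 1

    def __post_init__(self):
        if self.sk <= 0:
            raise ValueError("air-kerma strength must be positive")
        if self.dose_rate_constant <= 0:
            raise ValueError("dose-rate constant must be positive")
        if self.radial_dose:
            r, g = np.asarray(self.radial_dose, dtype=float).T
            if np.any(np.diff(r) <= 0):
                raise ValueError("radial dose table must have ascending radii")
            g1 = float(np.interp(1.0, r, g)) if r[0] <= 1.0 <= r[-1] else None
            if g1 is None or abs(g1 - 1.0) > 1e-6:
                raise ValueError("radial dose function must satisfy g(1 cm) = 1")

    def _eval(self, table, r):
        if not table:
            return np.ones_like(np.asarray(r, dtype=float))
        rr, vv = np.asarray(table, dtype=float).T
        r = np.asarray(r, dtype=float)
        if np.any(r < rr[0]) or np.any(r > rr[-1]):
            raise ValueError(f"radius outside tabulated range [{rr[0]}, {rr[-1]}] cm")
        return np.interp(r, rr, vv)

    def radial_dose_function(self, r):
        return self._eval(self.radial_dose, r)

    def anisotropy_factor(self, r):
        return self._eval(self.anisotropy, r)


def tg43_dose_rate(params: Tg43Params, r) -> float | np.ndarray:
    """Point-source TG-43 dose rate to water at radius ``r`` [cm], Gy/min."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("radius must be positive")
    cgy_per_h = (
        params.sk
        * params.dose_rate_constant
        * (1.0 / r_arr) ** 2
        * params.radial_dose_function(r_arr)
        * params.anisotropy_factor(r_arr)
    )
    out = cgy_per_h * CGY_PER_H_TO_GY_PER_MIN
    return out if np.ndim(r) else float(out)


def dose_rate_constant(dose_rate_at_1cm_gy_min: float, sk: float) -> float:
    """Dose-rate constant Lambda [cGy h^-1 U^-1] from the measured dose
    rate at 1 cm on the transverse bisector and the air-kerma strength."""
    if sk <= 0:
        raise ValueError("air-kerma strength must be positive")
    if dose_rate_at_1cm_gy_min <= 0:
        raise ValueError("dose rate must be positive")
    return dose_rate_at_1cm_gy_min / CGY_PER_H_TO_GY_PER_MIN / sk


def comparison_table(measured: list[tuple[float, float]], params: Tg43Params) -> pd.DataFrame:
    """Measured vs TG-43 dose rates with one-decimal percent differences.

    ``measured`` is a list of (radius cm, dose rate Gy/min) pairs.
    """
    rows = []
    for r, meas in measured:
        calc = tg43_dose_rate(params, r)
        diff = 100.0 * (meas - calc) / calc
        rows.append(
            {
                "r_cm": float(r),
                "measured_gy_min": float(meas),
                "tg43_gy_min": float(calc),
                "percent_diff": round(diff, 1),
            }
        )
    return pd.DataFrame(rows, columns=["r_cm", "measured_gy_min", "tg43_gy_min", "percent_diff"])
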