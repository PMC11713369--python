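"""Analytic photon interaction coefficient compilation.

Bundled coefficient tables are generated once from this module and shipped
as plain-text TSVs (see ``scripts/generate_physics_tables.py``).  The
compilation is built for the 30 keV - 1.5 MeV window that dominates
dosimetry around Ir-192 and Co-60 sources, where incoherent (Compton)
scattering carries almost the whole cross section in low-Z media:

* incoherent: exact free-electron Klein-Nishina, both the total cross
  section (closed form) and the energy-transfer moment (numerical
  quadrature of the differential cross section).  Electron binding
  (incoherent scattering function) is neglected.
* photoelectric: single power law ``Z^4.5 E^-3.2`` per element, anchored
  to the accepted low-energy water value; no absorption-edge structure.
* coherent (Rayleigh): ``Z^2.5 E^-2`` power law, again anchored on water.
  Coherent events change direction only and never transfer energy.
* pair production: linear-above-threshold ``Z^2 (E - 2 m_e c^2)`` law,
  anchored on water at 2 MeV; only the Co-60 lines are barely above
  threshold so this channel is a sub-0.2% correction.

The mass energy-absorption coefficient is assembled consistently from the
same channels (photoelectric and the electron share of pair fully local,
Klein-Nishina energy-transfer fraction for incoherent, nothing for
coherent); radiative losses of secondary electrons are neglected, so
``mu_en`` here is the energy-transfer coefficient ``mu_tr``.
"""

from __future__ import annotations

import numpy as np

from .constants import ELECTRON_REST_MEV, N_AVOGADRO, PAIR_THRESHOLD_MEV, R_ELECTRON_CM

# (Z, atomic mass) for every element used by the bundled materials
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "F": (9, 18.998),
    "Al": (13, 26.982),
    "Si": (14, 28.085),
    "Ar": (18, 39.948),
    "Fe": (26, 55.845),
    "Cu": (29, 63.546),
    "Ag": (47, 107.868),
}

# Anchor constants [cm^2/g], calibrated once on liquid water:
# photoelectric 4.94 cm^2/g at 10 keV, coherent 2.26e-2 at 30 keV,
# pair 3.91e-3 at 2 MeV.
_WATER_Z45 = 0.1119 * 1**4.5 / 1.008 + 0.8881 * 8**4.5 / 15.999
_WATER_Z25 = 0.1119 * 1**2.5 / 1.008 + 0.8881 * 8**2.5 / 15.999
_WATER_Z2 = 0.1119 * 1**2 / 1.008 + 0.8881 * 8**2 / 15.999
C_PHOTOELECTRIC = 4.94 / _WATER_Z45
C_COHERENT = 2.26e-2 / _WATER_Z25
C_PAIR = 3.91e-3 / (_WATER_Z2 * (2.0 - PAIR_THRESHOLD_MEV))

DEFAULT_GRID = np.geomspace(1e-3, 3.0, 81)


def kn_total_cross_section(energy_mev):
    """Klein-Nishina total cross section per electron [cm^2] (closed form)."""
    a = np.asarray(energy_mev, dtype=float) / ELECTRON_REST_MEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log1p(2 * a) / a)
    t2 = np.log1p(2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * R_ELECTRON_CM**2 * (t1 + t2 - t3)


def kn_differential_x(energy_mev, x):
    """Klein-Nishina dsigma/dx per electron, x = E'/E in [1/(1+2a), 1].

    Derived from dsigma/dOmega with the Compton relation
    ``1/x = 1 + a(1 - cos theta)``; the Jacobian gives
    ``dsigma/dx = (pi r_e^2 / a) (x + 1/x - sin^2 theta)``.
    """
    a = energy_mev / ELECTRON_REST_MEV
    cos_t = 1.0 - (1.0 / x - 1.0) / a
    sin2 = 1.0 - cos_t**2
    return np.pi * R_ELECTRON_CM**2 / a * (x + 1.0 / x - sin2)


def kn_energy_transfer_fraction(energy_mev, n_points: int = 4096):
    """Mean fraction of photon energy given to the Compton electron.

    Numerical quadrature of ``(1 - x) dsigma/dx`` over the kinematic range,
    normalized by the closed-form total cross section.
    """
    e = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    a = e / ELECTRON_REST_MEV
    x_min = 1.0 / (1.0 + 2.0 * a)
    u = np.linspace(0.0, 1.0, n_points)
    x = x_min[:, None] + (1.0 - x_min[:, None]) * u[None, :]
    f = kn_differential_x(e[:, None], x)
    total = np.trapezoid(f, x, axis=1)
    transfer = np.trapezoid((1.0 - x) * f, x, axis=1)
    out = transfer / total
    return out if np.ndim(energy_mev) else float(out[0])


def element_partials(symbol: str, energy_mev) -> dict[str, np.ndarray]:
    """Per-channel mass attenuation coefficients [cm^2/g] for one element."""
    if symbol not in ELEMENTS:
        raise KeyError(f"unknown element {symbol!r}")
    z, mass = ELEMENTS[symbol]
    e = np.asarray(energy_mev, dtype=float)
    electrons_per_g = N_AVOGADRO * z / mass
    incoherent = electrons_per_g * kn_total_cross_section(e)
    photoelectric = C_PHOTOELECTRIC * (z**4.5 / mass) * (0.01 / e) ** 3.2
    coherent = C_COHERENT * (z**2.5 / mass) * (0.03 / e) ** 2
    pair = C_PAIR * (z**2 / mass) * np.clip(e - PAIR_THRESHOLD_MEV, 0.0, None)
    return {
        "photoelectric": photoelectric,
        "incoherent": incoherent,
        "coherent": coherent,
        "pair": pair,
    }


def mixture_partials(composition, energy_mev) -> dict[str, np.ndarray]:
    """Mass-fraction weighted channel coefficients for a compound/mixture."""
    out: dict[str, np.ndarray] = {}
    for symbol, fraction in composition:
        for channel, value in element_partials(symbol, energy_mev).items():
            out[channel] = out.get(channel, 0.0) + fraction * value
    return out


def mixture_coefficients(composition, energy_mev=None):
    """Full coefficient set (total, energy absorption, partials) on a grid.

    Returns ``(energies, mu_over_rho, mu_en_over_rho, partials)``.
    """
    e = DEFAULT_GRID if energy_mev is None else np.asarray(energy_mev, dtype=float)
    partials = mixture_partials(composition, e)
    mu = sum(partials.values())
    f_tr = kn_energy_transfer_fraction(e)
    pair_fraction = np.where(e > 0, np.clip(e - PAIR_THRESHOLD_MEV, 0.0, None) / e, 0.0)
    mu_en = (
        partials["photoelectric"]
        + partials["incoherent"] * f_tr
        + partials["pair"] * pair_fraction
    )
    return e, mu, mu_en, partials


def electron_csda_range_water(energy_mev, i_excitation_ev: float = 75.0):
    """CSDA range in water [g/cm^2] from the Berger-Seltzer collision
    stopping power (no density effect, radiative losses ignored).

    Used only by the optional straight-line electron deposition model,
    where sub-percent range accuracy is irrelevant.
    """
    grid = np.geomspace(1e-3, 3.0, 400)
    tau = grid / ELECTRON_REST_MEV
    beta2 = 1.0 - 1.0 / (1.0 + tau) ** 2
    i_ratio = (i_excitation_ev * 1e-6) / ELECTRON_REST_MEV
    f_tau = 1.0 - beta2 + (tau**2 / 8.0 - (2 * tau + 1) * np.log(2.0)) / (tau + 1) ** 2
    # Z/A for water
    z_over_a = 0.55509
    arg = tau**2 * (tau + 2.0) / (2.0 * i_ratio**2)
    stopping = 0.153536 / beta2 * z_over_a * (np.log(arg) + f_tau)
    stopping = np.clip(stopping, 1e-3, None)
    ranges = np.concatenate([[0.0], np.cumsum(np.diff(grid) / stopping[1:])])
    return np.interp(np.asarray(energy_mev, dtype=float), grid, ranges)
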