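"""Bundled materials, photon coefficient tables, and source spectra.

Coefficient tables are plain-text TSVs under ``brachyq/data/coefficients``
(one per material, columns: energy [MeV], mu/rho, mu_en/rho and the four
per-interaction partial coefficients, all in cm^2/g).  Line spectra live
under ``brachyq/data/spectra`` as two-column text (MeV, relative
intensity).  Lookup between grid nodes is log-log linear and never
extrapolates: energies outside the grid raise.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

DATA_ROOT = resources.files("brachyq") / "data"

PARTIAL_CHANNELS = ("photoelectric", "incoherent", "coherent", "pair")


@dataclass(frozen=True)
class Material:
    """A medium: name, bulk density [g/cm^3] and elemental mass fractions."""

    name: str
    density: float
    composition: tuple[tuple[str, float], ...]

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        total = sum(f for _, f in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: mass fractions sum to {total}, not 1")


#: Media of the modeled detectors and phantoms.  C552 is air-equivalent
#: conducting plastic; "spc" approximates the silver-plated copper-covered
#: steel electrode of the A16 as a Fe/Cu/Ag mixture; "epoxy" is a generic
#: bisphenol epoxy potting resin.
MATERIALS: dict[str, Material] = {
    m.name: m
    for m in [
        Material("water", 0.998, (("H", 0.1119), ("O", 0.8881))),
        Material(
            "air",
            1.2048e-3,
            (("C", 0.000124), ("N", 0.755267), ("O", 0.231781), ("Ar", 0.012828)),
        ),
        Material("graphite", 1.70, (("C", 1.0),)),
        Material("pmma", 1.19, (("H", 0.080538), ("C", 0.599848), ("O", 0.319614))),
        Material(
            "c552",
            1.76,
            (
                ("H", 0.024680),
                ("C", 0.501610),
                ("O", 0.004527),
                ("F", 0.465209),
                ("Si", 0.003974),
            ),
        ),
        Material("aluminum", 2.699, (("Al", 1.0),)),
        Material("diamond", 3.52, (("C", 1.0),)),
        Material("epoxy", 1.20, (("H", 0.0703), ("C", 0.7161), ("O", 0.2136))),
        Material("spc", 8.30, (("Fe", 0.55), ("Cu", 0.33), ("Ag", 0.12))),
        Material("silver", 10.49, (("Ag", 1.0),)),
        Material("steel", 7.90, (("Fe", 0.70), ("C", 0.01), ("Cu", 0.29))),
    ]
}


@dataclass
class CoefficientTable:
    """Photon mass interaction coefficients on an ascending energy grid."""

    material: str
    energies: np.ndarray  # MeV, strictly ascending
    mu_over_rho: np.ndarray  # cm^2/g
    mu_en_over_rho: np.ndarray  # cm^2/g
    partials: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        for arr in (self.mu_over_rho, self.mu_en_over_rho, *self.partials.values()):
            if np.any(np.asarray(arr) < 0):
                raise ValueError("coefficients must be non-negative")

    def _interp(self, values: np.ndarray, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        lo, hi = self.energies[0], self.energies[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside {self.material} table range "
                f"[{lo:g}, {hi:g}] MeV"
            )
        with np.errstate(divide="ignore"):
            out = np.exp(
                np.interp(
                    np.log(e), np.log(self.energies), np.log(np.maximum(values, 1e-300))
                )
            )
        out = np.where(out < 1e-290, 0.0, out)
        return out if np.ndim(energy) else float(out)

    def attenuation(self, energy):
        return self._interp(self.mu_over_rho, energy)

    def energy_absorption(self, energy):
        return self._interp(self.mu_en_over_rho, energy)

    def partial(self, channel: str, energy):
        if channel not in self.partials:
            raise KeyError(f"unknown interaction channel {channel!r}")
        return self._interp(self.partials[channel], energy)

    @classmethod
    def from_file(cls, material: str, path) -> "CoefficientTable":
        raw = np.loadtxt(str(path))
        return cls(
            material=material,
            energies=raw[:, 0],
            mu_over_rho=raw[:, 1],
            mu_en_over_rho=raw[:, 2],
            partials={c: raw[:, 3 + i] for i, c in enumerate(PARTIAL_CHANNELS)},
        )


@functools.lru_cache(maxsize=None)
def get_table(material: str) -> CoefficientTable:
    """Load (and cache) the bundled coefficient table for a material."""
    if material not in MATERIALS:
        raise KeyError(f"unknown material {material!r}")
    path = DATA_ROOT / "coefficients" / f"{material}.tsv"
    return CoefficientTable.from_file(material, path)


def coefficient(material: str, energy, kind: str = "attenuation", channel: str | None = None):
    """Log-log interpolated mass coefficient [cm^2/g].

    ``kind`` is one of ``attenuation``, ``energy_absorption`` or
    ``partial`` (the latter requires ``channel``).  Exact table values are
    returned at grid nodes; energies outside the grid raise ``ValueError``.
    """
    table = get_table(material)
    if kind == "attenuation":
        return table.attenuation(energy)
    if kind == "energy_absorption":
        return table.energy_absorption(energy)
    if kind == "partial":
        if channel is None:
            raise ValueError("partial lookup requires a channel")
        return table.partial(channel, energy)
    raise ValueError(f"unknown coefficient kind {kind!r}")


@dataclass
class EnergySpectrum:
    """Discrete line spectrum: energies [MeV] with normalized intensities."""

    energies: np.ndarray
    intensities: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.energies.size == 0:
            raise ValueError("empty spectrum")
        if np.any(self.intensities < 0):
            raise ValueError("negative line intensity")
        total = self.intensities.sum()
        if total <= 0:
            raise ValueError("spectrum has zero total intensity")
        self.intensities = self.intensities / total
        self._cdf = np.cumsum(self.intensities)
        self._cdf[-1] = 1.0

    def sample_from_uniform(self, u: np.ndarray) -> np.ndarray:
        """Map uniforms in [0,1) to line energies through the CDF."""
        idx = np.searchsorted(self._cdf, np.asarray(u), side="right")
        return self.energies[np.clip(idx, 0, len(self.energies) - 1)]


def sample_energy(spectrum: EnergySpectrum, rng: np.random.Generator, size=None):
    """Draw photon energies from a line spectrum (inverse-CDF)."""
    u = rng.random(size)
    out = spectrum.sample_from_uniform(np.atleast_1d(u))
    return out if size is not None else float(out[0])


def mean_energy(spectrum: EnergySpectrum) -> float:
    """Intensity-weighted mean line energy [MeV]."""
    return float(np.sum(spectrum.energies * spectrum.intensities))


@functools.lru_cache(maxsize=None)
def load_spectrum(name: str) -> EnergySpectrum:
    """Bundled spectra: ``ir192`` (bare-nuclide gamma lines), the
    encapsulation-hardened variant ``ir192_encapsulated``, and ``co60``."""
    path = DATA_ROOT / "spectra" / f"{name}.tsv"
    try:
        raw = np.loadtxt(str(path), ndmin=2)
    except FileNotFoundError as err:
        raise KeyError(f"unknown spectrum {name!r}") from err
    return EnergySpectrum(raw[:, 0], raw[:, 1], name=name)
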