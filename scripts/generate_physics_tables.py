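"""Regenerate the bundled physics data files (coefficient tables, spectra).

Run from the repository root:

    python scripts/generate_physics_tables.py

Output is written into ``src/brachyq/data``; the repository ships the
generated files so nothing is computed or downloaded at install/test time.
A unit test asserts the bundled files match regeneration.
"""

from __future__ import annotations

import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from brachyq import _xsec  # noqa: E402
from brachyq.physics_data import MATERIALS, PARTIAL_CHANNELS  # noqa: E402

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "brachyq" / "data"

# Principal Ir-192 gamma lines: energy [MeV], emission probability per decay [%].
IR192_LINES = [
    (0.136343, 0.199),
    (0.201311, 0.473),
    (0.205794, 3.34),
    (0.283267, 0.266),
    (0.295957, 28.71),
    (0.308455, 29.70),
    (0.316506, 82.86),
    (0.374485, 0.726),
    (0.416469, 0.670),
    (0.468069, 47.84),
    (0.484575, 3.189),
    (0.489060, 0.438),
    (0.588581, 4.522),
    (0.604411, 8.216),
    (0.612462, 5.340),
    (0.884537, 0.291),
]

# Co-60 gamma lines.
CO60_LINES = [(1.17323, 0.9985), (1.33249, 0.9998)]

# Effective steel filter [cm] emulating capsule wall plus core self-absorption
# for the encapsulation-hardened Ir-192 spectrum variant.
CAPSULE_STEEL_CM = 0.040


def write_table(path: pathlib.Path, material) -> None:
    e, mu, mu_en, partials = _xsec.mixture_coefficients(material.composition)
    cols = [e, mu, mu_en] + [partials[c] for c in PARTIAL_CHANNELS]
    header = (
        f"{material.name}: photon mass interaction coefficients [cm^2/g]\n"
        f"density {material.density} g/cm^3; analytic compilation, "
        "exact Klein-Nishina incoherent channel\n"
        "energy_MeV mu_over_rho mu_en_over_rho " + " ".join(PARTIAL_CHANNELS)
    )
    np.savetxt(path, np.column_stack(cols), fmt="%.5e", header=header)


def write_spectrum(path: pathlib.Path, lines, title: str, weights=None) -> None:
    e = np.array([x[0] for x in lines])
    w = np.array([x[1] for x in lines], dtype=float)
    if weights is not None:
        w = w * weights
    w = w / w.sum()
    np.savetxt(
        path,
        np.column_stack([e, w]),
        fmt="%.6f %.8e",
        header=f"{title}\nenergy_MeV relative_intensity",
    )


def main() -> None:
    coeff_dir = DATA / "coefficients"
    spec_dir = DATA / "spectra"
    coeff_dir.mkdir(parents=True, exist_ok=True)
    spec_dir.mkdir(parents=True, exist_ok=True)

    for material in MATERIALS.values():
        write_table(coeff_dir / f"{material.name}.tsv", material)

    write_spectrum(spec_dir / "ir192.tsv", IR192_LINES, "Ir-192 bare-nuclide gamma lines")
    write_spectrum(spec_dir / "co60.tsv", CO60_LINES, "Co-60 gamma lines")

    steel = MATERIALS["steel"]
    e = np.array([x[0] for x in IR192_LINES])
    _, mu, _, _ = _xsec.mixture_coefficients(steel.composition, e)
    hardening = np.exp(-mu * steel.density * CAPSULE_STEEL_CM)
    write_spectrum(
        spec_dir / "ir192_encapsulated.tsv",
        IR192_LINES,
        "Ir-192 lines hardened by an effective steel capsule filter",
        weights=hardening,
    )
    print(f"wrote {len(MATERIALS)} coefficient tables and 3 spectra under {DATA}")


if __name__ == "__main__":
    main()
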