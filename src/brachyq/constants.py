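"""Physical constants and unit conversions used across the package.

All transport internals work in MeV, cm, g and unit-density-free mass
coefficients (cm^2/g); doses are converted to Gy only at the tally surface.
"""

# Electron rest energy [MeV]
ELECTRON_REST_MEV = 0.51099895

# Classical electron radius [cm]
R_ELECTRON_CM = 2.8179403262e-13

# Avogadro constant [1/mol]
N_AVOGADRO = 6.02214076e23

# Pair-production threshold [MeV]
PAIR_THRESHOLD_MEV = 2.0 * ELECTRON_REST_MEV

# 1 MeV/g expressed in Gy (J/kg)
MEV_PER_G_TO_GY = 1.602176634e-10

# Air-kerma strength unit: 1 U = 1 uGy m^2/h = 1 cGy cm^2/h.
# Dose-rate constants are quoted in cGy h^-1 U^-1, so Sk [U] * Lambda
# [cGy/h/U] is a dose rate in cGy/h at 1 cm.
CGY_PER_H_TO_GY_PER_MIN = 0.01 / 60.0
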