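# brachyq

Beam-quality correction factors and dosimetry around high-dose-rate
¹⁹²Ir brachytherapy sources.

Clinical reference dosimetry calibrates ionization chambers in a ⁶⁰Co
beam, but measurements in a water phantom around an ¹⁹²Ir source happen
in a very different radiation quality: a softer, distance-dependent
photon spectrum with steep 1/r² gradients that large chambers average
over.  The conversion is the beam-quality correction factor

> k_Q,Qo = [D_w / D̄_det]_Q / [D_w / D̄_det]_Qo · (R_Qo / R_Q)

— the double ratio of dose-to-water to mean detector dose between the
¹⁹²Ir quality Q (point source centered in a 30 cm water sphere,
detector at y = 1…10 cm on the transverse bisector) and the ⁶⁰Co
reference quality Qo (10 × 10 cm² field, 100 cm, 5 cm depth) — which
then enters the calibration dose equation
D_w,Q = M_Q · N_D,w,Qo · k_Q,Qo.

The package is aimed at medical physicists doing brachytherapy
dosimetry audits or detector studies.  It provides:

* a vectorized Monte Carlo photon transport engine (track-length kerma
  scoring, correlated shared-seed runs, directional importance
  sampling, counter-based reproducible randomness, optional
  straight-line electron kernel) over CSG models of ten commercial
  detectors built from their published dimensions;
* the k_Q,Qo formalism and the stem/electrode/wall/replacement
  perturbation-factor decomposition;
* a point-source TG-43 engine (Ḋ(r) = S_K·Λ·g(r)·φ_an(r)/r²),
  dose-rate-constant extraction and measured-vs-calculated tables;
* the ionometric protocol: k_TP, polarity and two-voltage
  recombination corrections, scan-based chamber alignment, and a GUM
  uncertainty budget;
* synthetic electrometer data generators so every stage runs with no
  external inputs.

See `docs/methods.md` for models, approximations and limitations.

## Worked example

```python
from brachyq import EngineOptions, compute_kq, compute_perturbations

opts = EngineOptions(n_histories=600_000)
res = compute_kq("30013", 1.0, seed=5, opts=opts)   # PTW Farmer at 1 cm
print(f"kQ,Qo = {res.kq:.3f} ± {res.kq_stderr:.3f}")
print(f"  [Dw/Ddet] Ir-192 @1cm : {res.dose_ratio_q:.3f}")
print(f"  [Dw/Ddet] Co-60 ref   : {res.dose_ratio_qo:.3f}")

p = compute_perturbations("30013", 1.0, seed=5, opts=opts)
print(f"p_repl = {p.p_repl[0]:.3f} ± {p.p_repl[1]:.3f}")
```

prints (about a minute on one core):

```
kQ,Qo = 1.331 ± 0.013
  [Dw/Ddet] Ir-192 @1cm : 1.461
  [Dw/Ddet] Co-60 ref   : 1.098
p_repl = 1.461 ± 0.006
```

Read: at 1 cm the Farmer chamber's 0.6 cm³ cavity averages the steeply
falling 1/r² dose, so it under-responds by ~46% relative to a point
water voxel in the ¹⁹²Ir field, while in the flat ⁶⁰Co reference field
the ratio is just the water/air energy-absorption contrast (~1.10);
their quotient says readings taken at 1 cm must be scaled up by ~1.3.
The replacement factor p_repl isolates the same volume-averaging plus
cavity fluence perturbation.  Under this engine's kerma-level physics
these values run a few percent above published full-electron-transport
results (see `docs/methods.md`); the effect directions, distance
trends, and the small-chamber values near unity match.

A TG-43 example with no Monte Carlo:

```python
from brachyq import Tg43Params, tg43_dose_rate, dose_rate_constant
params = Tg43Params(sk=21954.50, dose_rate_constant=1.109)
tg43_dose_rate(params, 1.0)          # 4.0579 Gy/min at 1 cm
dose_rate_constant(4.0765, 21954.50) # 1.1141 cGy/(h·U)
```

There is also a CLI (`brachyq kq|perturbations|tg43|protocol|fixtures
--config cfg.yaml --seed N --out-dir out`) that writes CSV tables plus
a run manifest.

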