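# PTW 60019 microDiamond: 2.2 mm diameter disc, ~1 um thick sensitive
# volume (4e-3 mm^3); diamond window + epoxy in front, diamond base
# behind acting as the "stem". No central electrode is modeled.
name: "60019"
nominal_volume_mm3: 4.0e-3
cavity: {shape: disc, diameter: 2.2, length: 1.05e-3, gas: diamond}
wall:
  - {material: diamond, thickness: 0.3}
  - {material: epoxy, thickness: 0.614}
electrode: null
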