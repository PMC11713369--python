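# PTW 30013 Farmer chamber
name: "30013"
nominal_volume_mm3: 600
cavity: {shape: cylinder, diameter: 5.5, length: 23.0, gas: air}
wall:
  - {material: graphite, thickness: 0.09}
  - {material: pmma, thickness: 0.34}
electrode: {material: aluminum, diameter: 1.1}
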