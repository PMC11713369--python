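# PTW 31010 Semiflex, medium cavity
name: "31010"
nominal_volume_mm3: 125
cavity: {shape: cylinder, diameter: 5.5, length: 6.5, gas: air}
wall:
  - {material: graphite, thickness: 0.15}
  - {material: pmma, thickness: 0.55}
electrode: {material: aluminum, diameter: 1.1}
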