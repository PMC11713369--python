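# PTW 31014 PinPoint: small cylindrical cavity, graphite/PMMA wall
name: "31014"
nominal_volume_mm3: 15
cavity: {shape: cylinder, diameter: 2.0, length: 5.0, gas: air}
wall:
  - {material: graphite, thickness: 0.09}
  - {material: pmma, thickness: 0.57}
electrode: {material: aluminum, diameter: 0.3}
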