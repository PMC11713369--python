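# PTW 31016 PinPoint 3D
name: "31016"
nominal_volume_mm3: 16
cavity: {shape: cylinder, diameter: 2.9, length: 2.9, gas: air}
wall:
  - {material: graphite, thickness: 0.09}
  - {material: pmma, thickness: 0.57}
electrode: {material: aluminum, diameter: 0.3}
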