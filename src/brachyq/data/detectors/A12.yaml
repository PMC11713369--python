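# Exradin A12 Farmer chamber, C552 wall and electrode
name: "A12"
nominal_volume_mm3: 640
cavity: {shape: cylinder, diameter: 6.1, length: 25.8, gas: air}
wall:
  - {material: c552, thickness: 0.5}
electrode: {material: c552, diameter: 1.0}
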