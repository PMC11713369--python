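# IBA CC01G small cavity chamber
name: "CC01G"
nominal_volume_mm3: 10
cavity: {shape: cylinder, diameter: 2.0, length: 3.6, gas: air}
wall:
  - {material: c552, thickness: 0.5}
electrode: {material: graphite, diameter: 0.6}
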