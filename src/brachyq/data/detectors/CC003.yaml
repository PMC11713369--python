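# IBA CC003: spherical 2 mm cavity with spherical graphite electrode
name: "CC003"
nominal_volume_mm3: 3
cavity: {shape: sphere, diameter: 2.0, gas: air}
wall:
  - {material: c552, thickness: 0.5}
electrode: {material: graphite, diameter: 1.0}
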