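# Exradin A16 micro chamber; silver-plated copper-covered steel electrode
name: "A16"
nominal_volume_mm3: 7
cavity: {shape: cylinder, diameter: 3.4, length: 2.5, gas: air}
wall:
  - {material: c552, thickness: 0.5}
electrode: {material: spc, diameter: 0.3}
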