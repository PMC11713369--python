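# Co-60 gamma lines
# energy_MeV relative_intensity
1.173230 4.99674724e-01
1.332490 5.00325276e-01
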