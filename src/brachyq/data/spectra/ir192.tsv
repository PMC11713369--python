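# Ir-192 bare-nuclide gamma lines
# energy_MeV relative_intensity
0.136343 9.17981364e-04
0.201311 2.18193560e-03
0.205794 1.54073254e-02
0.283267 1.22705047e-03
0.295957 1.32438417e-01
0.308455 1.37005259e-01
0.316506 3.82230833e-01
0.374485 3.34901744e-03
0.416469 3.09069102e-03
0.468069 2.20684565e-01
0.484575 1.47107667e-02
0.489060 2.02048159e-03
0.588581 2.08598579e-02
0.604411 3.79001753e-02
0.612462 2.46332688e-02
0.884537 1.34237476e-03
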