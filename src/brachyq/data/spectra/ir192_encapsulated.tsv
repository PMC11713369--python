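# Ir-192 lines hardened by an effective steel capsule filter
# energy_MeV relative_intensity
0.136343 8.83944074e-04
0.201311 2.15300984e-03
0.205794 1.52154579e-02
0.283267 1.22232913e-03
0.295957 1.32044768e-01
0.308455 1.36705184e-01
0.316506 3.81572428e-01
0.374485 3.35247825e-03
0.416469 3.09863374e-03
0.468069 2.21595504e-01
0.484575 1.47779721e-02
0.489060 2.02994578e-03
0.588581 2.10037139e-02
0.604411 3.81729733e-02
0.612462 2.48142457e-02
0.884537 1.35741252e-03
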