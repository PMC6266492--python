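# Conversion factors for the packaged eight-city study region.
equivalence:
  arable: 2.51
  forest: 1.26
  pasture: 0.46
  water: 0.37
  fossil_energy: 1.26
  built_up: 2.51
yield_factors:
  arable: 1.66
  pasture: 0.19
  forest: 0.91
  built_up: 1.66
  water: 1.00
  fossil_energy: 0.0
biodiversity_fraction: 0.12
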