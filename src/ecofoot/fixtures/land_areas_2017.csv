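land_type,area_hm2
arable,2099120
pasture,3662319
forest,224336
built_up,1431049
fossil_energy,0
water,806220
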