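year,ef_per_capita,ec_per_capita,available_ec_per_capita,deficit_per_capita
2013,1.527,0.3478,0.306,1.2209
2014,1.4782,0.3795,0.334,1.1442
2015,2.3897,0.4084,0.3594,2.0303
2016,1.9143,0.3902,0.3434,1.571
2017,1.2611,0.3595,0.3164,0.9447
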