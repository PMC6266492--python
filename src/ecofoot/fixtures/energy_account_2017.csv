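item,land_type,global_avg_energy_footprint_GJ_per_hm2,convert_coefficient_GJ_per_t,Nanjing,Wuxi,Suzhou,Changzhou,Zhenjiang,Nantong,Yangzhou,Taizhou
Raw coal,fossil_energy,55,20.934,27859054,25585565,52930655,10259787,18853868,21035064,10472274,15794328
Washed coal,fossil_energy,55,26.344,5853334,2278006,7678792,0,589212,0,0,92656
Other coal washing,fossil_energy,55,8.363,1351,0,5739,0,16,0,127900,0
Coke,fossil_energy,55,28.47,6556289,4048528,12288290,5097035,602498,145694,0,35106.89
Other fuel,fossil_energy,55,8.363,0,654,11260,0,0,0,973226,0
Gasoline,fossil_energy,93,43.124,27186,26571,66250,9251,17312,36007,32259,14989.41
Kerosene,fossil_energy,93,43.124,248,840,2442,105,44234,4085,299,6098.19
Diesel,fossil_energy,93,42.705,72969,63961,151720,12528,14349,51910,56542,51012.43
Fuel oil,fossil_energy,71,50.16,6527,105213,123981,0,2084,28937,5333,146327.89
Other petroleum products,fossil_energy,71,50.16,12128828,2469,3753,0,1767,0,47573,683.63
Liquefied petroleum gas,fossil_energy,71,50.16,366100,2273,8820,1128,22337,71849,3290,28020.12
Natural gas,fossil_energy,93,38.979,236540,224033,401984,143123,0,16869,81930,0
Electricity,built_up,1000,11.84,3126235,4092900,9196802,4299322,1583368,1353245,1563203,1761311.9
Heat,built_up,1000,29.34,95201693,77784760,108628412,27632015,25559810,54357115,16960399,201282559
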