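item,land_type,global_avg_yield_kg_per_hm2,in_demand_aggregate,Nanjing,Nantong,Zhenjiang,Yangzhou,Wuxi,Suzhou,Taizhou,Changzhou
Paddy,arable,2744,true,768375,1605397,776916,287290,271938,665632,371938,864312
Wheat,arable,2744,true,234638,961731,347308,1033943,197818,285282,197818,389792
Corn,arable,2744,true,40952,330116,33594,12337,16994,9294,12495,27895
Beans,arable,1856,true,14554,129871,16105,53770,7032,4544,8819,15308
Potato,arable,12607,true,21400,19596,12292,14636,14957,13885,7032,1024
Cotton,arable,1000,true,3071,23797,910,1144,1365,500,520,371
Oil,arable,1856,true,74337,358183,58291,68669,2212,13409,2212,24144
Vegetables,arable,18000,true,2149606,4390975,1766902,2068921,45896,39896,45896,2714920
Melon and fruit,arable,18000,false,243237,577994,144101,92825,176222,95595,176222,103312
Pig,pasture,74,true,53150,256366,47686,98677,51665,61778,51665,39842
Cow,pasture,33,true,832,313,12716,638,38,467,38,679
Sheep,pasture,33,true,2603,26518,19075,1866,319,1982,319,39842
Aquatic products,water,29,true,223098,890285,99896,401183,13995,254918,197393,166351
Milk,pasture,502,true,74721,21441,18046,12665,26290,102957,26290,19823
Honey,pasture,50,true,259,296,365,652,203,397,203,459
Egg,pasture,400,true,65367,447700,27775,137404,27017,38030,27017,39624
Tea,forest,826.1377,true,1540,0,1756,6861,6507,361,0,2585
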