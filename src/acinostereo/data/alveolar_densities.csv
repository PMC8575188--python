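animal_id,day,assessed_acini,average,sd,minimum,maximum
04A,4,51,3124,1152,1618,8208
04B,4,23,1363,499,679,2704
04C,4,51,1569,380,799,2775
10A,10,27,2685,1022,1246,5582
10B,10,14,3091,1166,1890,5422
10C,10,17,2848,1462,1182,7009
21B,21,14,2642,493,1625,3344
21D,21,17,2534,895,1111,4032
21E,21,11,3119,775,1604,4379
60B,60,24,1249,297,530,1912
60D,60,10,838,271,476,1221
60E,60,9,898,323,411,1463
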