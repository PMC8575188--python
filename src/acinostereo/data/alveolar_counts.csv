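animal_id,day,assessed_acini,average,sd,minimum,maximum
04A,4,51,26.73,23.56,4,111
04B,4,23,65.04,43.85,15,171
04C,4,51,60.51,45.42,10,249
10A,10,27,77.85,56.31,18,245
10B,10,14,84.57,65.75,23,199
10C,10,17,108.76,125.45,15,505
21B,21,14,208.14,197.71,35,781
21D,21,17,196.00,128.56,50,493
21E,21,11,323.09,145.94,108,572
60B,60,24,701.75,230.95,322,1296
60D,60,10,668.30,121.67,444,810
60E,60,9,739.11,281.22,272,1204
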