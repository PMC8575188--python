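animal_id,day,assessed_acini,average,sd,minimum,maximum
04A,4,51,0.009,0.008,0.002,0.035
04B,4,23,0.058,0.053,0.008,0.194
04C,4,51,0.044,0.044,0.006,0.275
10A,10,27,0.033,0.026,0.004,0.108
10B,10,14,0.033,0.030,0.004,0.096
10C,10,17,0.057,0.084,0.002,0.333
21B,21,14,0.087,0.086,0.011,0.322
21D,21,17,0.109,0.112,0.014,0.380
21E,21,11,0.118,0.072,0.025,0.238
60B,60,24,0.588,0.223,0.226,1.104
60D,60,10,0.888,0.350,0.364,1.576
60E,60,9,0.977,0.526,0.186,1.875
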