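grid,value
0.0,1.0060286380721934
15.0,0.5569768017166276
30.0,0.2499142240457024
45.0,0.3599711062789799
60.0,0.3168790666715372
75.0,0.17568234759030038
90.0,0.20671723236693326
105.0,0.1941017257425269
120.0,0.1531010092659758
135.0,0.18922470515706272
150.0,0.2414942165215302
165.0,0.22352996272244402
180.0,0.11802035476381845
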