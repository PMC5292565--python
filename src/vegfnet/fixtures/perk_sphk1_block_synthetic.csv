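grid,value
0.0,0.05405703555802382
5.0,0.015738829022254586
10.0,-0.011200578796092877
15.0,-0.0617131579775699
20.0,-0.0005828965353725413
25.0,0.08150575402702633
30.0,-0.02191763688286773
35.0,-0.04911616139139388
40.0,-0.0018551574673754752
45.0,0.034245515901154655
50.0,-0.05805071781985378
55.0,-0.025573110149145508
60.0,-0.04677402412448216
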