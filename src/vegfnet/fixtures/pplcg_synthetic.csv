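grid,value
0.0,0.03337794831086749
5.0,1.0485326392529464
10.0,0.989518580886074
15.0,1.036896106248274
20.0,0.9934113527487717
25.0,0.9004953996622419
30.0,0.9122838934388816
35.0,1.0229909008318359
40.0,1.01777236632687
45.0,0.8931498640311714
50.0,0.8708969774262824
55.0,0.8787618641421808
60.0,0.9128563436027854
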