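grid,value
0.5,-0.004749359493621355
1.0,0.054685831430067486
2.0,-0.005390427657939966
5.0,0.08127333689073206
10.0,0.12153508340738907
20.0,0.18029414449655318
50.0,0.3312206668188248
200.0,0.5992238906020583
1000.0,1.0104509899762557
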