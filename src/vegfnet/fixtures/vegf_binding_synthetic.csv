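grid,value
0.5,-0.0015135853086828324
1.0,0.08353663892255961
2.0,-0.007269361163732703
5.0,0.1060588440483133
10.0,0.09258317842090696
20.0,0.22129452163537938
50.0,0.38180735001639593
200.0,0.5842429479594553
1000.0,0.9850857742726385
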