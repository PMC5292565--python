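grid,value
0.0,0.9721603816522908
5.0,0.46618950926708147
10.0,0.3250833891861963
15.0,0.2883536412433372
20.0,0.25073681782623264
25.0,0.30039179977017144
30.0,0.25719194767671716
35.0,0.284973556040184
40.0,0.29332451403926696
45.0,0.23058790060344006
50.0,0.19184808730130745
55.0,0.263026486201391
60.0,0.2346867647624751
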