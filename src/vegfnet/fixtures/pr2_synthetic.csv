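grid,value
0.0,0.016382646109754703
5.0,0.4058283030961531
10.0,0.4669094412937397
15.0,0.40153649261177515
20.0,0.2796094347095103
25.0,0.3289841426079033
30.0,0.26549156546176944
35.0,0.20210272873429952
40.0,0.1737933021983025
45.0,0.18552268977762712
50.0,0.1837567175658537
55.0,0.10958409971415205
60.0,0.16158181167150643
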