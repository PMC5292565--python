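grid,value
0.0,0.026085466347651885
5.0,1.0165955671249332
10.0,0.9759168887997605
15.0,1.013738637363133
20.0,0.9603601421944822
25.0,0.8886682675396032
30.0,1.0560437395569742
35.0,1.0275971136404314
40.0,0.9544352538912172
45.0,1.0142201339694945
50.0,0.9859025361219236
55.0,0.9964889306526474
60.0,1.0161538569767024
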