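grid,value
0.5,-0.01429415808110298
1.0,0.03663867762673723
2.0,0.056756531986622276
5.0,0.021299371930713292
10.0,1.0551528449595007
20.0,1.0008155478957854
50.0,0.978022504421776
200.0,0.9751902638415048
1000.0,1.0007731289759412
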