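grid,value
0.0,0.05508672865945854
2.5,0.11269048299818754
5.0,0.29032660661229137
7.5,0.2947319757158799
10.0,0.3660790273273592
12.5,0.3508048616329179
15.0,0.3887673874871941
17.5,0.3344639902117572
20.0,0.31352819768491264
22.5,0.30399281609324025
25.0,0.33432967316599566
27.5,0.2742115497056582
30.0,0.32228944098209056
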