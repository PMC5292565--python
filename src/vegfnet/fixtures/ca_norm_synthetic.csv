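grid,value
0.0,0.09854352765096797
2.5,0.19369744244110737
5.0,0.8846301375942843
7.5,0.9430898349353345
10.0,0.9938000638349339
12.5,1.0163367832651051
15.0,0.9747564035885182
17.5,1.0036734202393822
20.0,0.9372842402850388
22.5,0.9753340891980276
25.0,0.992437969673461
27.5,0.966242478132542
30.0,0.954444863021021
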