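grid,value
0.0,0.9563865768906884
15.0,0.43331282961303696
30.0,0.17971476649659635
45.0,0.061206302852318
60.0,0.08986976133054753
75.0,0.061522302971132245
90.0,0.07938970848229215
105.0,0.11817174692362842
120.0,0.028610984795110296
135.0,0.02110075781315762
150.0,0.058511389516927935
165.0,0.03601792826268672
180.0,0.07129673523342837
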