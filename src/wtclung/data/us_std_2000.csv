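age_low,age_high,weight
0,1,0.013818
1,5,0.055317
5,15,0.145565
15,25,0.138646
25,35,0.135573
35,45,0.162613
45,55,0.134834
55,65,0.087247
65,75,0.066037
75,85,0.044842
85,inf,0.015508
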