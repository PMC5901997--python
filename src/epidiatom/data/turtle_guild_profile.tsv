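sample	high_profile	low_profile	motile	planktonic
1	5.9	12.9	80.7	0.5
2	12.5	5.2	81.2	1.2
3	4.0	13.2	82.8	0.0
4	11.5	17.6	70.0	0.9
5	6.5	9.2	84.3	0.0
6	3.9	14.2	80.0	1.9
7	3.9	12.7	83.5	0.0
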