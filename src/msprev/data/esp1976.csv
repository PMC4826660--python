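age_band_5yr,weight
0-4,8000
5-9,7000
10-14,7000
15-19,7000
20-24,7000
25-29,7000
30-34,7000
35-39,7000
40-44,7000
45-49,7000
50-54,7000
55-59,6000
60-64,5000
65-69,4000
70-74,3000
75-79,2000
80-84,1000
85+,1000
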