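# Expert field-evaluation totals (percentage scale, 0-100) for the 37 Sichuan
# pilot areas; area k corresponds to policy Pk.
area_id,total
1,87.66
2,92.33
3,84.55
4,91.59
5,95.42
6,77.59
7,94.8
8,88.03
9,90.32
10,84.06
11,88.32
12,90.33
13,90.59
14,93.15
15,88.83
16,87.36
17,88.75
18,93.58
19,91.07
20,91.72
21,89.68
22,88.31
23,85.54
24,78.66
25,93.33
26,86.89
27,89.3
28,80.15
29,86.58
30,78.84
31,95.85
32,81.25
33,77.94
34,97.94
35,78.33
36,90.85
37,88.76
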