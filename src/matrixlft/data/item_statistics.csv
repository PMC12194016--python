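item,rules,p,item_rest_r,m_tot,m_onset,m_inter,m_intra
1,2,0.54,0.31,43.14,21.76,12.51,8.33
2,2,0.57,0.44,46.78,23.64,9.76,2.91
3,2,0.53,0.51,50.19,28.19,14.95,1.72
4,2,0.16,0.46,56.69,32.67,14.23,1.84
5,2,0.33,0.64,53.72,29.75,17.77,1.33
6,2,0.30,0.41,58.18,25.62,24.71,2.47
7,2,0.39,0.49,53.44,24.95,20.20,4.06
8,2,0.51,0.48,47.23,24.45,18.22,1.33
9,2,0.13,0.49,52.77,22.96,24.24,2.66
10,2,0.15,0.51,54.15,33.53,11.96,1.87
11,2,0.59,0.63,39.46,17.28,14.92,1.43
12,3,0.32,0.52,50.60,17.82,14.36,1.81
13,3,0.16,0.58,61.33,31.18,15.42,2.03
14,3,0.46,0.59,53.83,17.24,15.26,0.77
15,3,0.43,0.64,50.45,15.19,13.71,0.86
16,3,0.35,0.69,50.24,13.76,16.69,1.52
17,3,0.39,0.79,48.30,12.61,15.90,1.36
18,3,0.61,0.63,47.01,18.16,10.83,1.18
19,4,0.21,0.49,55.03,14.07,13.20,1.74
20,4,0.30,0.60,53.01,11.22,13.38,2.54
21,4,0.26,0.67,55.05,12.25,14.08,1.46
22,5,0.21,0.53,57.86,12.87,13.35,1.42
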