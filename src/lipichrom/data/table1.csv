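compound_id,MLogP,ALogP,LogP99,LogPcons_AlvaDesc,LogP_Chemicalize,iLogP,XLogP3,WLogP,SilicosIT,LogPcons_SwissADME,CHI_LogP
1,2.15,2.40,2.04,2.20,2.49,2.92,2.57,1.98,1.59,2.19,3.48
2,1.89,2.38,2.05,2.11,2.33,3.40,2.55,1.99,1.65,2.23,4.44
3,2.86,3.72,3.35,3.31,3.70,3.32,3.83,3.29,2.88,3.18,3.27
4,2.64,3.06,2.70,2.80,3.09,3.27,3.2,2.64,2.23,2.74,3.97
5,2.60,3.43,2.82,2.95,3.45,3.36,3.29,2.76,2.37,2.82,3.70
6,2.32,3.41,2.83,2.86,3.29,3.58,3.26,2.77,2.44,2.81,3.49
7,3.29,4.76,4.13,4.06,4.66,4.03,4.54,4.07,3.66,3.86,4.63
8,3.08,4.10,3.48,3.55,4.06,3.71,3.92,3.42,3.01,3.37,3.98
9,1.86,2.17,1.61,1.88,2.21,3.12,1.90,1.55,1.25,1.78,2.91
10,2.43,2.82,2.22,2.49,2.83,3.18,2.55,2.16,1.81,2.28,3.10
11,3.29,4.34,3.98,3.87,4.44,3.77,4.54,3.92,3.40,3.72,4.55
12,2.81,3.89,3.21,3.30,3.90,3.68,3.65,3.15,2.77,3.16,3.98
13,2.53,3.87,3.22,3.21,3.74,3.86,3.62,3.16,2.84,3.14,3.76
14,2.53,3.87,3.22,3.21,3.74,3.92,3.62,3.16,2.84,3.15,3.92
15,2.53,3.87,3.22,3.21,3.74,3.96,3.62,3.16,2.84,3.16,3.76
16,3.29,4.55,3.87,3.90,4.50,3.94,4.27,3.81,3.41,3.69,4.58
17,3.29,4.55,3.87,3.90,4.50,3.92,4.27,3.81,3.41,3.69,4.49
18,3.50,5.22,4.52,4.41,5.10,4.20,4.90,4.46,4.05,4.17,4.93
19,3.60,4.83,4.23,4.22,4.77,4.01,4.53,5.32,3.86,4.21,4.69
20,3.18,4.09,3.35,3.54,4.04,3.70,3.75,3.71,3.19,3.45,4.19
21,3.49,4.80,4.37,4.22,4.89,4.11,4.90,4.31,3.79,4.06,4.91
22,2.65,3.28,2.61,2.84,3.27,3.47,2.91,2.55,2.20,2.61,3.44
23,2.09,2.63,2.00,2.24,2.65,3.33,2.26,1.94,1.64,2.10,3.37
24,3.00,4.64,3.82,3.82,4.56,4.03,4.38,3.76,3.85,3.70,4.33
25,3.16,4.75,4.43,4.11,4.77,4.09,4.66,4.37,4.42,4.12,4.40
26,2.72,3.84,3.36,3.31,3.92,3.54,3.48,3.00,2.81,3.05,3.93
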