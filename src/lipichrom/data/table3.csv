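compound_id,CHI_pH2.6,CHI_pH7.4,CHI_pH10.6,CHI_IAM,LogK_HSA,pct_HSA
1,48.96,88.07,91.64,36.93,0.74,85.32
2,60.08,110.90,109.41,46.90,1.72,99.13
3,49.19,78.80,87.69,35.71,0.52,77.60
4,56.31,100.82,100.70,42.61,1.32,96.38
5,52.20,89.50,95.60,39.09,0.84,88.23
6,52.94,79.45,91.77,38.03,0.68,83.59
7,72.79,112.26,112.92,48.28,1.77,99.31
8,97.99,101.36,100.81,44.30,1.53,98.11
9,48.71,74.93,81.12,34.40,0.58,79.78
10,38.96,76.74,84.51,35.73,0.72,84.71
11,63.51,104.83,111.43,47.26,1.67,98.90
12,55.26,93.84,100.78,41.59,1.00,91.87
13,54.89,84.12,96.78,40.54,0.42,73.28
14,55.41,94.73,99.75,41.42,0.93,90.46
15,55.04,87.50,96.78,40.04,0.65,82.67
16,61.89,108.61,111.92,46.73,1.71,99.06
17,61.34,106.56,110.38,46.32,1.57,98.36
18,65.39,119.04,118.39,50.19,2.27,<99.80
19,63.86,113.75,114.05,46.84,1.85,99.61
20,57.21,97.64,104.68,42.69,1.00,91.90
21,65.07,109.08,118.03,48.85,1.75,99.25
22,43.25,82.33,90.87,38.48,0.55,78.60
23,41.03,80.76,89.54,34.77,-0.05,47.66
24,60.18,102.90,107.33,45.78,1.23,95.36
25,60.65,101.68,108.64,45.96,1.57,98.37
26,55.76,100.20,100.01,41.48,1.19,94.87
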