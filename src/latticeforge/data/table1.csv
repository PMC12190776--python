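case_id,lrtv_cc,vortex_cc,valley_cc,vortex_ratio_pct,vortex_dose_gy,valley_dose_gy,vpdr_pct,peripheral_dose_gy
1,45.35,1.75,38.89,3.86,12.14,8.69,71.52,4.17
2,114.50,8.07,104.70,7.05,11.78,7.77,65.93,4.20
3,1257.50,80.60,1178.40,6.41,11.88,8.19,68.96,5.16
4,218.70,9.90,208.20,4.53,12.04,7.76,64.41,5.26
5,127.39,4.40,121.70,3.45,12.08,7.61,63.04,4.18
6,513.36,20.60,488.70,4.01,11.96,7.22,60.34,4.67
7,64.19,6.10,57.00,9.50,11.96,9.20,76.92,6.07
8,335.66,22.71,307.90,6.77,11.90,8.39,70.50,6.12
9,411.62,34.89,374.00,8.47,11.88,8.68,73.09,5.28
10,357.03,37.23,315.40,10.43,11.86,8.86,74.71,6.19
11,1863.40,181.91,1674.30,9.76,11.93,9.51,79.75,6.79
12,383.00,24.07,358.64,6.29,11.88,8.11,68.23,4.63
13,179.40,15.19,162.60,8.47,11.96,8.19,68.51,5.35
14,377.20,22.89,351.20,6.07,11.80,7.35,62.29,5.01
15,316.43,28.14,285.20,8.89,11.75,9.31,79.29,5.80
16,156.86,14.39,140.35,9.17,11.95,8.44,70.61,4.66
17,219.90,21.31,196.20,9.69,11.91,8.52,71.52,5.20
18,201.47,11.83,189.50,5.87,12.05,7.43,61.64,3.16
19,123.50,11.08,111.30,8.97,11.93,8.09,67.70,4.60
20,505.20,34.62,469.30,6.85,11.96,7.05,58.99,4.22
21,337.50,27.51,306.30,8.15,11.96,8.89,74.37,5.42
22,1020.90,99.00,917.90,9.69,11.98,9.05,75.53,6.25
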