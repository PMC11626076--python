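# Scan settings and reference objective image-quality values for the
# three anthropomorphic phantoms at the 13-level kVp/mA protocol
# (rotation/exposure time 0.28 s). *_ref columns are reference values
# for report schemas and round-trip tests, not recomputed quantities.
scan_id,phantom,kvp,ma,rotation_time,ctdi_vol,scan_length,ap_diameter,ml_diameter,mas_ref,cnr_ref,snr_ref,median_steepness_ref
1,adult,140,50,0.28,1.59,36,26.0,26.0,14.0,18.64,17.27,5324.49
2,adult,140,40,0.28,1.2,36,26.0,26.0,11.2,17.25,16.06,3995.02
3,adult,140,30,0.28,0.95,36,26.0,26.0,8.4,16.35,15.22,2673.91
4,adult,140,20,0.28,0.63,36,26.0,26.0,5.6,15.58,14.46,2195.73
5,adult,140,10,0.28,0.32,36,26.0,26.0,2.8,13.19,12.19,1297.25
6,adult,120,20,0.28,0.44,36,26.0,26.0,5.6,14.15,13.14,1590.85
7,adult,120,10,0.28,0.22,36,26.0,26.0,2.8,13.03,11.99,885.54
8,adult,100,20,0.28,0.27,36,26.0,26.0,5.6,13.4,12.33,937.71
9,adult,100,10,0.28,0.14,36,26.0,26.0,2.8,12.3,11.43,713.28
10,adult,80,20,0.28,0.14,36,26.0,26.0,5.6,11.24,10.47,572.3
11,adult,80,10,0.28,0.07,36,26.0,26.0,2.8,9.78,9.85,474.95
12,adult,70,20,0.28,0.09,36,26.0,26.0,5.6,10.51,10.68,397.29
13,adult,70,10,0.28,0.04,36,26.0,26.0,2.8,7.17,8.39,257.97
14,paediatric,140,50,0.28,1.43,16,25.0,25.0,14.0,24.3,24.36,3451.98
15,paediatric,140,40,0.28,1.14,16,25.0,25.0,11.2,24.91,25.01,3271.14
16,paediatric,140,30,0.28,0.86,16,25.0,25.0,8.4,22.08,22.16,3070.61
17,paediatric,140,20,0.28,0.57,16,25.0,25.0,5.6,17.96,17.99,2681.34
18,paediatric,140,10,0.28,0.29,16,25.0,25.0,2.8,16.12,16.08,1962.56
19,paediatric,120,20,0.28,0.4,16,25.0,25.0,5.6,15.06,15.25,2318.57
20,paediatric,120,10,0.28,0.2,16,25.0,25.0,2.8,14.96,15.15,1505.04
21,paediatric,100,20,0.28,0.25,16,25.0,25.0,5.6,14.88,15.24,1775.2
22,paediatric,100,10,0.28,0.13,16,25.0,25.0,2.8,15.16,15.46,1139.83
23,paediatric,80,20,0.28,0.13,16,25.0,25.0,5.6,12.89,13.46,1195.68
24,paediatric,80,10,0.28,0.07,16,25.0,25.0,2.8,11.84,12.26,685.0
25,paediatric,70,20,0.28,0.09,16,25.0,25.0,5.6,11.64,12.27,743.76
26,paediatric,70,10,0.28,0.04,16,25.0,25.0,2.8,9.63,10.33,651.23
27,neonate,140,50,0.28,1.19,10,,,14.0,75.46,74.09,2478.05
28,neonate,140,40,0.28,0.95,10,,,11.2,66.58,65.45,2477.14
29,neonate,140,30,0.28,0.71,10,,,8.4,55.17,54.02,2455.41
30,neonate,140,20,0.28,0.48,10,,,5.6,45.74,45.03,2601.04
31,neonate,140,10,0.28,0.24,10,,,2.8,36.22,35.39,2399.42
32,neonate,120,20,0.28,0.33,10,,,5.6,42.33,41.8,2386.29
33,neonate,120,10,0.28,0.17,10,,,2.8,30.8,30.34,2084.18
34,neonate,100,20,0.28,0.21,10,,,5.6,34.33,33.9,2375.71
35,neonate,100,10,0.28,0.1,10,,,2.8,27.07,26.99,2089.35
36,neonate,80,20,0.28,0.11,10,,,5.6,27.52,27.54,2082.85
37,neonate,80,10,0.28,0.06,10,,,2.8,21.06,21.04,1690.77
38,neonate,70,20,0.28,0.07,10,,,5.6,24.8,25.06,1824.99
39,neonate,70,10,0.28,0.04,10,,,2.8,18.91,19.19,1101.76
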