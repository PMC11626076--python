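# Size-dependent conversion factors keyed by effective diameter (cm).
# ssde_factor: dimensionless multiplier applied to CTDIvol (32 cm reference
#   phantom) -> SSDE, exponential fit a*exp(-b*d), a=3.704369, b=0.03671937.
# ed_factor: mSv per mGy*cm applied to DLP -> effective dose; chest-region
#   factors anchored at d=25 cm (0.0384615) and d=26 cm (0.0257937) and
#   extended smoothly (exp slope -0.04/cm). Replace with your own table for
#   other body regions or age groups.
effective_diameter_cm,ssde_factor,ed_factor
8,2.761456,0.0759184
9,2.661896,0.0729416
10,2.565926,0.0700815
11,2.473415,0.0673336
12,2.38424,0.0646934
13,2.29828,0.0621567
14,2.215419,0.0597195
15,2.135546,0.0573779
16,2.058552,0.0551281
17,1.984335,0.0529665
18,1.912793,0.0508896
19,1.84383,0.0488942
20,1.777354,0.046977
21,1.713274,0.045135
22,1.651505,0.0433653
23,1.591962,0.0416649
24,1.534567,0.0400312
25,1.47924,0.0384615
26,1.425909,0.0257937
27,1.3745,0.0247823
28,1.324945,0.0238105
29,1.277176,0.0228769
30,1.231129,0.0219799
31,1.186743,0.0211181
32,1.143957,0.02029
33,1.102713,0.0194944
34,1.062957,0.01873
35,1.024633,0.0179956
36,0.987692,0.01729
37,0.952082,0.0166121
38,0.917757,0.0159607
39,0.884668,0.0153349
40,0.852773,0.0147336
41,0.822028,0.0141559
42,0.792391,0.0136008
43,0.763822,0.0130675
44,0.736284,0.0125551
45,0.709738,0.0120628
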