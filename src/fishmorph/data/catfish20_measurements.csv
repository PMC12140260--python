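index,manual_FL,manual_BL,manual_BH,manual_BT,manual_HL,manual_THH,manual_THW,auto_FL,auto_BL,auto_BH,auto_BT,auto_HL,auto_THH,auto_THW
1,15.97,12.919,2.429,2.12,3.406,1.735,1.102,15.258,12.914,2.378,2.448,3.653,1.564,1.281
2,14.963,11.877,2.007,2.094,3.129,1.597,1.055,14.252,11.713,2.048,2.248,3.173,1.431,0.903
3,14.988,12.122,2.398,2.135,3.126,1.726,1.1,15.434,12.696,2.144,2.343,3.46,1.833,0.607
4,14.155,11.317,2.286,2.056,2.698,1.489,1.005,14.118,11.666,2.125,2.34,3.25,1.521,1.028
5,16.342,13.457,2.6,2.352,3.211,1.952,1.183,15.916,13.399,2.378,2.429,3.364,1.934,1.245
6,14.161,11.342,2.211,2.143,2.741,1.596,0.977,13.6,12.188,2.038,2.095,3.047,1.429,1.401
7,13.569,11.09,2.189,2.033,2.704,1.515,0.961,12.521,10.808,2.038,2.084,3.06,1.131,1.08
8,14.67,11.616,3.365,2.094,2.903,1.092,1.51,14.167,11.798,2.183,2.389,3.252,1.58,1.18
9,12.949,10.234,2.028,1.847,2.517,1.504,0.89,12.174,10.064,1.868,1.832,2.443,1.248,0.617
10,12.98,10.336,2.159,1.845,2.52,1.326,0.961,12.717,10.781,2.048,2.002,2.867,1.421,0.627
11,15.248,12.069,2.478,2.274,2.902,1.748,1.069,14.857,12.452,2.374,2.503,2.865,1.655,0.949
12,13.792,11.058,2.486,2.146,2.79,1.507,1.073,13.59,11.216,2.32,2.301,3.363,1.361,1.597
13,13.071,10.216,2.184,1.858,2.518,1.581,0.897,12.961,10.94,2.041,1.932,2.891,1.523,1.276
14,15.81,12.613,2.537,2.224,2.935,1.741,1.033,16.129,12.927,2.38,2.482,3.384,1.746,1.507
15,15.466,12.471,2.43,2.231,2.748,1.69,1.115,15.828,12.559,2.38,2.454,2.71,1.926,1.097
16,16.51,13.137,2.921,2.427,3.18,2.03,1.139,16.099,13.133,2.463,2.508,3.267,1.842,1.1
17,12.971,10.334,2.22,1.894,2.38,1.424,0.962,12.163,10.4,2.133,1.989,2.431,1.368,1.143
18,12.235,9.566,1.894,1.885,2.398,1.439,0.81,11.393,9.405,2.04,2.095,2.748,1.391,1.051
19,12.012,9.544,2.072,1.824,2.453,1.067,0.811,11.408,9.131,1.828,1.764,2.432,1.113,1.216
20,10.446,8.466,1.717,1.554,2.107,1.202,0.745,11.249,9.16,1.787,1.437,2.539,1.153,1.122
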