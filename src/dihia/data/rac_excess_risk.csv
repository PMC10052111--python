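risk_percent,exposure_low,exposure_high
0.1,0.0,0.025
0.5,0.027,0.040
1.0,0.055,0.070
2.0,0.12,0.19
3.0,0.22,0.33
4.0,0.40,0.48
5.0,0.67,
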