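sector,mean_exposed
construction,5700
motor_vehicle,9300
polyurethane,1700
assembly,1500
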