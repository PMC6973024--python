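study,yi,vi
trial_1,0.314,0.05
trial_2,1.056,0.1
trial_3,0.072,0.2
trial_4,1.006,0.08
trial_5,0.236,0.12
trial_6,0.345,0.15
trial_7,0.593,0.06
trial_8,-0.56,0.1
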