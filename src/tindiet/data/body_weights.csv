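age_group,kg
le6,19.9
7_12,33.7
13_17,52.3
18_59,62.1
ge60,60.4
total,57.0
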