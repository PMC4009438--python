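Left vs Stop,Right vs Stop,Forward vs Stop,Back vs Stop
98.4,98.7,81.1,86.5
99.8,99.2,79.1,84.1
93.2,94.7,81.2,85.4
97.7,96.5,80.1,80.8
98.1,88.2,81.2,86.9
91.1,99.5,84.2,86.6
99.2,98.1,77.2,81.1
98.0,98.2,83.1,87.1
91.2,90.4,80.2,83.1
85.0,84.1,74.1,76.3
94.5,95.2,82.8,86.1
90.1,94.0,78.2,79.3
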