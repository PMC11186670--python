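time,environment,height_cm,width_cm,hull_volume_cm3
1,greenhouse,27.3,44.8,16091.3
2,greenhouse,27.5,44.5,15705.8
3,greenhouse,27.4,45.0,16029.8
4,greenhouse,27.4,44.7,15690.3
5,greenhouse,27.4,44.7,15561.6
6,field,27.7,45.1,15610.0
7,field,27.7,44.9,15473.0
8,field,27.4,45.1,14791.0
9,field,27.8,45.2,15774.0
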