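leaf,leaf_length_cm,blade_length_cm,blade_width_cm
1,26.1,15.6,9.9
2,27.7,14.4,8.3
3,29.3,17.8,9.2
4,30.5,15.9,8.8
5,28.1,14.6,8.7
6,33.1,16.7,10.1
7,29.5,14.2,9.5
8,23.7,10.4,7.2
9,23.4,12.1,6.3
10,19.5,9.0,4.7
11,18.8,9.3,2.2
12,14.7,7.4,1.9
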