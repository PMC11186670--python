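leaf,auto_leaf_length_cm,auto_blade_length_cm,auto_blade_width_cm,auto_leaf_angle_deg,auto_leaf_area_cm2,manual_leaf_length_cm,manual_blade_length_cm,manual_blade_width_cm,manual_leaf_angle_deg
1,25.4,14.6,9.1,108.7,100.9,27.6,15.6,9.3,104.0
2,26.4,12.0,8.2,65.7,69.6,25.9,14.2,8.4,63.0
3,27.8,14.8,9.2,87.0,92.9,26.4,15.5,10.1,85.0
4,29.0,13.5,8.3,42.3,80.7,29.1,14.4,9.1,42.0
5,27.5,14.3,8.7,21.9,90.7,31.9,16.7,10.5,20.0
6,32.0,16.6,10.2,47.8,121.2,28.4,14.4,9.4,49.0
7,29.1,14.4,9.3,40.4,90.7,27.6,16.1,9.1,41.0
8,23.5,11.6,7.2,28.8,60.6,22.3,11.1,7.0,30.0
9,22.4,10.4,6.8,26.7,51.0,23.4,11.6,7.8,18.0
10,17.9,8.9,4.8,19.8,30.5,18.0,9.3,4.9,12.0
11,17.9,7.4,2.3,17.4,10.0,17.9,8.0,2.4,10.0
12,14.0,8.1,2.3,10.8,10.4,13.1,7.5,1.9,4.0
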