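leaf,sigma_laser_mm,sigma_camera_mm,n_laser,n_camera,n_reference,pct_laser,pct_camera
1,0.24,1.18,363,382,393,-7.6,-2.8
2,0.20,0.57,267,306,314,-14.9,-2.5
3,0.20,0.48,399,387,427,-6.6,-9.4
4,0.22,0.47,297,340,326,-8.9,4.3
5,0.34,0.28,322,366,377,-14.6,-2.9
6,0.32,0.32,354,355,369,-4.1,-3.8
7,0.77,0.29,321,362,378,-15.1,-4.2
8,0.12,0.20,204,205,210,-2.9,-2.4
9,0.37,0.32,226,229,243,-7.0,-5.8
10,0.07,0.36,110,106,123,-10.6,-13.8
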