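mean_nucleus_diameter_px,pixels_per_um
5.235,0.6
5.239,0.6
7.465,0.9
7.819,0.9
9.093,1.1
9.248,1.1
12.241,1.5
12.339,1.5
16.391,2.0
16.497,2.0
22.028,2.75
22.211,2.75
28.167,3.5
28.381,3.5
36.813,4.55
37.087,4.55
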