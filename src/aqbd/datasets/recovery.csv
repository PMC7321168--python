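impurity,level_pct,added_ugml,found_ugml,recovery_printed_pct
A,0.05,0.2633,0.2747,104.33
A,0.15,0.7899,0.8252,104.47
A,0.18,0.9479,0.9923,104.68
B,0.05,0.2599,0.2685,103.32
B,0.15,0.7797,0.806,103.37
B,0.18,0.9356,0.9766,104.38
C,0.05,0.2625,0.2687,102.35
C,0.15,0.7875,0.808,102.6
C,0.18,0.945,0.9709,102.74
D,0.05,0.2519,0.2613,103.75
D,0.15,0.7556,0.7853,103.93
D,0.18,0.9068,0.9435,104.05
E,0.05,0.2521,0.2578,102.27
E,0.15,0.7564,0.7829,103.51
E,0.18,0.9076,0.947,104.34
F,0.05,0.2476,0.2606,105.22
F,0.15,0.7429,0.7782,104.74
F,0.18,0.8915,0.9323,104.57
G,0.05,0.2427,0.2437,100.43
G,0.15,0.7281,0.7446,102.27
G,0.18,0.8737,0.8992,102.91
H,0.05,0.2482,0.2554,102.88
H,0.15,0.7447,0.778,104.46
H,0.18,0.8937,0.9339,104.5
chloro,0.05,0.2476,0.2713,109.57
chloro,0.15,0.7429,0.7871,105.95
chloro,0.18,0.8915,0.9301,104.33
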