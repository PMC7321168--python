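run_id,temperature_C,methanol_pct,gradient_slope,T,R1,R2,R3,R4,R5
N14,48.5,39,2.8,2.56,2.28,1.82,2.68,3.77,-3.33
N1,40,32,1.6,2.99,2.52,1.85,2.53,4.17,0.01
N9,48.5,32,2.2,2.80,2.36,1.76,3.04,3.35,-0.04
N10,48.5,46,2.2,2.78,2.21,2.70,1.64,6.26,-1.01
N7,57,32,2.8,2.65,2.18,1.81,3.04,2.91,0.01
N16,48.5,39,2.2,2.79,2.29,2.20,2.40,4.72,-0.89
N8,57,46,2.8,2.63,2.05,2.66,1.95,5.64,-0.96
N13,48.5,39,1.6,3.06,2.29,2.70,1.83,6.15,2.55
N3,57,32,1.6,3.15,2.21,2.60,2.56,5.08,5.36
N17,48.5,39,2.2,2.78,2.30,2.21,2.34,4.75,-1.08
N11,40,39,2.2,2.66,2.43,1.76,2.35,4.09,-3.58
N6,40,46,2.8,2.46,2.33,1.91,1.86,4.75,-5.85
N2,40,46,1.6,2.94,2.34,2.85,0.07,7.24,0.01
N15,48.5,39,2.2,2.78,2.30,2.18,2.48,4.64,-0.13
N5,40,32,2.8,2.49,2.46,0.91,2.93,1.60,-5.46
N4,57,46,1.6,3.11,2.04,3.53,1.11,7.82,5.30
N12,57,39,2.2,2.84,2.14,2.56,2.28,5.14,1.67
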