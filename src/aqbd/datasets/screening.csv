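run_id,buffer_mM,buffer_pH,temperature_C,methanol_pct,initial_b_pct,gradient_slope,T,R1,R2,R3,R4,R5
N14,10,3,55,40,5,0.8,5.15,0.97,4.08,0.10,9.96,10.97
N18,25,2.5,45,30,7.5,1.6,3.40,2.06,1.86,2.97,3.99,0.30
N11,40,2,55,20,10,0.8,3.33,2.63,1.72,3.89,4.07,9.17
N6,10,3,35,40,5,2.4,3.43,1.37,1.51,2.07,3.87,-8.96
N10,10,2,55,40,10,2.4,3.42,1.54,2.37,2.42,5.09,-3.59
N13,10,3,55,20,10,0.8,4.54,1.34,1.76,3.56,4.55,6.00
N2,10,2,35,40,10,0.8,3.83,1.84,2.75,0.10,8.28,0.99
N8,40,3,35,40,10,0.8,3.36,2.48,2.58,0.94,7.62,4.96
N4,40,2,35,40,5,2.4,2.48,2.56,1.39,2.50,3.42,-5.67
N1,10,2,35,20,5,0.8,4.22,1.91,2.19,1.71,5.47,3.24
N3,40,2,35,20,10,2.4,2.55,2.87,0.10,4.41,-0.73,-5.88
N19,25,2.5,45,30,7.5,1.6,3.39,2.04,1.89,2.92,4.11,0.10
N9,10,2,55,20,5,2.4,3.29,1.59,1.43,3.71,1.64,-2.03
N17,25,2.5,45,30,7.5,1.6,3.41,2.06,1.84,3.01,3.95,0.79
N12,40,2,55,40,5,0.8,3.61,2.10,3.99,0.10,9.36,14.12
N16,40,3,55,40,10,2.4,2.90,2.18,2.14,2.74,4.58,0.10
N15,40,3,55,20,5,2.4,2.84,2.19,1.12,4.17,0.88,1.79
N7,40,3,35,20,5,0.8,3.66,2.54,1.87,2.36,4.55,6.96
N5,10,3,35,20,10,2.4,3.45,1.57,0.10,3.56,0.10,-8.94
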