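name,from,to,dist,mean,min,max
k_12_10,10,12,normal,12,0.85,22
k_1_10,10,1,normal,10,0.52,20
k_2_10,10,2,normal,1.9,0.14,3.6
k_3_10,10,3,normal,0.47,0.034,0.90
k_7_10,10,7,normal,3.5,0.26,6.7
k_6_10,10,6,normal,3.5,0.26,6.7
k_14_10,10,14,normal,0.35,0.026,0.67
k_11_10,10,11,normal,1.4,0.10,2.7
k_17_10,10,17,normal,0.12,0.0085,0.22
k_0_10,10,0,normal,8.2e-3,5.9e-4,1.6e-2
k_18_10,10,18,normal,0.47,0.034,0.90
k_10_13,13,10,normal,9.5e-4,3.6e-4,1.5e-3
k_11_12,12,11,normal,2.3e-3,7.1e-4,3.9e-3
k_13_12,12,13,normal,2.1e-2,7.9e-3,3.4e-2
k_10_1,1,10,normal,1.4,0.53,2.24
k_10_2,2,10,normal,1.9e-3,7.2e-4,3.07e-3
k_10_3,3,10,normal,1.3e-4,4.8e-5,2.05e-4
k_10_9,9,10,normal,7.6e-3,2.9e-3,1.23e-2
k_9_7,7,9,normal,8.0e-5,3.1e-5,1.33e-4
k_5_7,7,5,normal,4.0e-5,1.6e-5,6.7e-5
k_9_5,5,9,normal,8.0e-5,3.1e-5,1.3e-4
k_10_8,8,10,normal,7.6e-3,2.9e-3,1.2e-2
k_8_6,6,8,normal,4.9e-4,1.9e-4,8.0e-4
k_4_6,6,4,normal,2.5e-4,9.4e-5,4.0e-4
k_8_4,4,8,normal,4.9e-4,1.9e-4,8.0e-4
k_18_14,14,18,normal,9.9e-2,3.8e-2,1.6e-1
k_10_17,17,10,normal,1.4e-3,5.3e-4,2.2e-3
k_10_0,0,10,normal,3.8e-4,1.5e-4,6.2e-4
k_24_18,18,24,normal,12,4.6,19
k_25_23,23,25,normal,1.5,0.71,2.2
k_23_21,21,23,normal,1.6,0.83,2.4
k_21_16,16,21,normal,1.6,0.83,2.4
k_16_11,11,16,normal,4.1,1.9,6.4
k_10_11,11,10,normal,2.3e-3,5.1e-5,4.5e-3
k_11_15,15,11,normal,25,3.5,47
k_15_19,19,15,normal,1.6e4,5.9e3,2.5e4
k_15_20,20,15,normal,2.9e2,1.1e2,4.7e2
k_19_22,22,19,normal,3.87e4,1.53e4,6.3e4
k_20_22,22,20,normal,4.3e3,1.7e3,7.0e3
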