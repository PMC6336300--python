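plot,x_meas,y_meas,x_est,y_est
1,3.10,-2.88,3.23,-2.84
1,3.17,0.21,3.28,0.12
1,3.52,1.70,3.47,1.74
1,3.41,3.12,3.49,3.07
1,3.62,4.56,3.62,4.69
1,1.15,3.23,1.24,3.31
1,1.24,4.80,1.22,4.90
1,-4.04,3.43,-3.99,3.52
1,-3.97,2.22,-4.06,2.15
1,-1.67,0.57,-1.66,0.48
1,-4.19,0.84,-4.14,0.77
1,-4.10,-0.76,-4.18,-0.80
1,-1.99,-0.96,-1.92,-1.02
1,-4.40,-3.81,-4.49,-3.89
1,-1.76,-2.53,-1.84,-2.46
1,0.71,-2.79,0.63,-2.73
2,3.70,-2.25,3.54,-2.29
2,3.36,-1.06,3.33,-1.03
2,3.13,2.11,3.18,2.16
2,0.57,1.88,0.56,1.85
2,0.43,3.43,0.47,3.50
2,-1.26,4.95,-1.35,4.99
2,-1.49,3.34,-1.45,3.43
2,-1.41,2.01,-1.49,2.01
2,-4.01,0.75,-4.16,0.69
2,-4.45,-3.69,-4.41,-3.79
2,-1.58,-2.34,-1.62,-2.28
2,-1.59,-3.96,-1.55,-3.93
2,3.11,-4.27,3.05,-4.35
3,2.67,-3.59,2.62,-3.55
3,2.20,-2.10,2.27,-2.16
3,4.90,-3.00,5.03,-3.05
3,4.44,-1.84,4.53,-1.88
3,4.36,-0.29,4.31,-0.38
3,3.74,0.89,3.84,0.84
3,3.64,3.45,3.71,3.58
3,1.45,2.10,1.45,2.01
3,1.12,3.31,1.21,3.38
3,1.36,4.82,1.30,4.90
3,-1.20,3.05,-1.20,3.13
3,-1.29,1.62,-1.23,1.58
3,-3.41,3.41,-3.38,3.34
3,-3.47,1.72,-3.40,1.78
3,-3.35,0.30,-3.40,0.24
3,-3.41,-2.19,-3.46,-2.28
3,-3.60,-3.74,-3.65,-3.65
3,-1.14,-2.60,-1.21,-2.66
3,-1.42,-3.90,-1.48,-4.03
4,-2.01,4.24,-1.96,4.29
4,-1.90,2.54,-1.83,2.61
4,-4.32,4.12,-4.39,4.19
4,-1.76,1.18,-1.79,1.16
4,-1.62,-0.28,-1.57,-0.24
4,-1.42,-1.61,-1.48,-1.55
4,-1.50,-3.46,-1.45,-3.35
4,-1.46,-4.65,-1.40,-4.77
4,0.94,-4.52,0.99,-4.58
4,0.90,-3.14,0.97,-3.11
4,3.09,-4.62,3.03,-4.71
4,3.06,-3.11,3.12,-3.20
4,3.12,-0.30,3.22,-0.35
4,3.18,1.18,3.25,1.14
4,3.66,2.42,3.59,2.48
4,0.92,1.15,0.98,1.08
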