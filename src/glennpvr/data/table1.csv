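pid,sex,bsa,age,q_svc,q_lpa,q_rpa,pvr_cath,qp_cath,p_svc,p_lpa,p_rpa,p_la,p_ra
1,M,0.64,4,1.71,0.65,1.13,1.87,2.14,11,9,10,5,5
2,M,0.66,5,1.31,0.66,0.63,1.38,2.9,7,7,7,3,3
3,M,0.6,5,1.27,0.63,0.65,3.8,1.84,12,12,12,5,4
4,F,0.51,4,2.31,1.12,1.22,2.21,2.26,9,9,8,4,4
5,F,0.55,4,1.85,0.65,1.20,2.18,3.22,11,11,11,4,4
6,F,0.63,5,1.23,0.52,0.70,2.04,2.93,10,10,10,4,4
7,M,0.67,5,1.92,1.05,0.90,1.22,2.47,7,7,7,4,4
8,F,0.57,5,1.49,0.80,0.70,1.72,2.33,8,8,8,4,4
9,M,0.52,3,1.65,0.74,0.86,2.81,1.78,9,8,9,4,3
10,M,0.49,4,3.13,1.98,1.14,1.4,2.14,9,8,8,5,5
11,M,0.54,3,2.02,0.55,1.44,1.3,3.07,11,11,11,7,5
12,F,0.55,3,2.16,1.36,0.77,1.12,2.67,8,8,7,4,4
13,M,0.53,3,1.81,0.58,1.22,1.63,2.45,8,7,8,3,3
14,M,0.7,4,2.17,0.98,1.15,2.12,1.89,9,8,9,5,5
15,F,0.49,3,2.90,1.45,1.50,1.37,3.64,10,10,10,5,5
16,M,0.31,2,2.60,1.84,0.77,0.68,5.89,10,9,9,5,6
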