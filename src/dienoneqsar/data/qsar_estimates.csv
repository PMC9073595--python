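compound_id,cell_line,observed_ic50,estimated_ic50,error
24,HCT116,1.08,1.17,-0.09
24,MCF7,1.83,1.39,0.44
24,A431,2.49,1.94,0.55
25,HCT116,1.03,0.95,0.08
25,MCF7,2.09,2.50,-0.41
25,A431,2.51,2.21,0.30
26,HCT116,1.43,1.39,0.04
26,MCF7,2.48,2.50,-0.02
26,A431,2.83,2.80,0.03
27,HCT116,1.61,1.29,0.32
27,MCF7,2.95,2.62,0.33
27,A431,2.56,4.25,-1.69
28,HCT116,1.31,1.60,-0.29
28,MCF7,2.58,2.51,0.07
28,A431,2.58,2.65,-0.07
29,HCT116,0.70,0.72,-0.02
29,MCF7,1.33,1.58,-0.25
29,A431,1.29,1.08,0.21
30,HCT116,0.58,0.60,-0.02
30,MCF7,1.13,0.89,0.24
30,A431,0.64,0.92,-0.28
31,HCT116,1.03,0.88,0.15
31,MCF7,1.44,1.54,-0.10
31,A431,1.24,1.81,-0.57
32,HCT116,1.04,0.91,0.13
32,MCF7,2.35,2.12,0.23
32,A431,1.31,1.39,-0.08
33,HCT116,1.13,0.93,0.20
33,MCF7,2.14,2.00,0.14
33,A431,1.45,1.76,-0.31
34,HCT116,0.56,0.59,-0.03
34,MCF7,2.34,2.07,0.27
34,A431,1.27,1.00,0.27
35,HCT116,0.56,0.53,0.03
35,MCF7,1.36,1.46,-0.10
35,A431,1.20,1.07,0.13
36,HCT116,0.62,0.69,-0.07
36,MCF7,1.71,2.18,-0.47
36,A431,1.31,0.98,0.33
37,HCT116,0.57,0.63,-0.06
37,MCF7,2.32,2.51,-0.19
37,A431,1.18,1.03,0.15
38,HCT116,0.56,0.56,0.00
38,MCF7,2.16,2.53,-0.37
38,A431,1.33,1.38,-0.05
39,HCT116,1.44,1.36,0.08
39,MCF7,3.96,4.46,-0.50
39,A431,2.57,2.79,-0.22
40,HCT116,2.73,2.87,-0.14
40,MCF7,5.10,4.52,0.58
40,A431,4.90,6.04,-1.14
41,HCT116,2.26,3.71,-1.45
41,MCF7,4.58,4.87,-0.29
41,A431,2.64,3.32,-0.68
42,HCT116,22.98,3.43,19.55
42,MCF7,4.90,5.10,-0.20
42,A431,8.75,6.78,1.97
43,HCT116,1.23,1.29,-0.06
43,MCF7,3.96,4.38,-0.42
43,A431,2.72,3.09,-0.37
44,HCT116,1.11,0.94,0.17
44,MCF7,4.17,3.94,0.23
44,A431,2.85,3.18,-0.33
45,HCT116,1.38,1.55,-0.17
45,MCF7,5.85,5.82,0.03
45,A431,11.35,10.62,0.73
46,HCT116,1.50,1.71,-0.21
46,MCF7,5.73,5.13,0.60
46,A431,8.83,5.63,3.20
47,HCT116,1.29,1.72,-0.43
47,MCF7,4.89,4.74,0.15
47,A431,7.98,6.53,1.45
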