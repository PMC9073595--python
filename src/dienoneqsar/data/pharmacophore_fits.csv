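compound_id,cell_line,observed_ic50,estimated_ic50,fit_value
24,HCT116,1.08,0.86,6.951
24,MCF7,1.83,2.25,6.069
24,A431,2.49,3.77,7.029
25,HCT116,1.03,1.03,6.874
25,MCF7,2.09,2.80,5.975
25,A431,2.51,1.25,7.508
26,HCT116,1.43,1.00,6.885
26,MCF7,2.48,2.62,6.002
26,A431,2.83,1.21,7.524
27,HCT116,1.61,0.69,7.043
27,MCF7,2.95,2.64,5.999
27,A431,2.56,2.58,7.194
28,HCT116,1.31,1.43,6.731
28,MCF7,2.58,2.19,6.082
28,A431,2.58,3.74,7.032
29,HCT116,0.70,0.93,6.917
29,MCF7,1.33,2.93,5.954
29,A431,1.29,2.31,7.242
30,HCT116,0.58,0.72,7.029
30,MCF7,1.13,2.59,6.008
30,A431,0.64,1.56,7.412
31,HCT116,1.03,1.75,6.643
31,MCF7,1.44,2.89,5.960
31,A431,1.24,2.02,7.300
32,HCT116,1.04,2.31,6.521
32,MCF7,2.35,3.14,5.924
32,A431,1.31,1.65,7.387
33,HCT116,1.13,1.27,6.780
33,MCF7,2.14,3.08,5.933
33,A431,1.45,3.86,7.019
34,HCT116,0.56,0.88,6.942
34,MCF7,2.34,2.03,6.114
34,A431,1.27,2.42,7.221
35,HCT116,0.56,0.70,7.040
35,MCF7,1.36,1.82,6.162
35,A431,1.20,1.46,7.442
36,HCT116,0.62,0.62,7.094
36,MCF7,1.71,1.84,6.156
36,A431,1.31,1.84,7.341
37,HCT116,0.57,0.49,7.198
37,MCF7,2.32,2.21,6.077
37,A431,1.18,1.62,7.396
38,HCT116,0.56,0.48,7.203
38,MCF7,2.16,2.46,6.030
38,A431,1.33,1.46,7.440
39,HCT116,1.44,2.05,6.574
39,MCF7,3.96,3.74,5.848
39,A431,2.57,3.62,7.046
40,HCT116,2.73,1.43,6.730
40,MCF7,5.10,3.04,5.939
40,A431,4.90,1.87,7.333
41,HCT116,2.26,2.02,6.581
41,MCF7,4.58,3.85,5.836
41,A431,2.64,3.58,7.052
42,HCT116,22.98,11.50,5.824
42,MCF7,4.90,3.21,5.914
42,A431,8.75,5.18,6.891
43,HCT116,1.23,1.18,6.814
43,MCF7,3.96,2.76,5.981
43,A431,2.72,2.61,7.189
44,HCT116,1.11,2.43,6.500
44,MCF7,4.17,3.45,5.883
44,A431,2.85,1.60,7.401
45,HCT116,1.38,1.19,6.808
45,MCF7,5.85,3.10,5.929
45,A431,11.35,5.11,6.897
46,HCT116,1.50,1.24,6.791
46,MCF7,5.73,3.65,5.859
46,A431,8.83,5.26,6.885
47,HCT116,1.29,2.98,6.411
47,MCF7,4.89,3.72,5.850
47,A431,7.98,3.07,7.118
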