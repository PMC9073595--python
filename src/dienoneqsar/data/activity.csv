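compound_id,assay,ic50_um,sd_um,censor,is_reference
24,HCT116,1.08,0.18,exact,0
24,MCF7,1.83,0.14,exact,0
24,A431,2.49,0.31,exact,0
24,RPE1,16.63,1.57,exact,0
25,HCT116,1.03,0.29,exact,0
25,MCF7,2.09,0.26,exact,0
25,A431,2.51,0.24,exact,0
25,RPE1,22.07,2.06,exact,0
26,HCT116,1.43,0.20,exact,0
26,MCF7,2.48,0.31,exact,0
26,A431,2.83,0.36,exact,0
26,RPE1,17.72,1.98,exact,0
27,HCT116,1.61,0.14,exact,0
27,MCF7,2.95,0.24,exact,0
27,A431,2.56,0.29,exact,0
27,RPE1,50.00,3.02,greater_than,0
28,HCT116,1.31,0.22,exact,0
28,MCF7,2.58,0.30,exact,0
28,A431,2.58,0.27,exact,0
28,RPE1,11.96,1.76,exact,0
29,HCT116,0.70,0.06,exact,0
29,MCF7,1.33,0.24,exact,0
29,A431,1.29,0.15,exact,0
29,RPE1,9.67,2.03,exact,0
30,HCT116,0.58,0.07,exact,0
30,MCF7,1.13,0.29,exact,0
30,A431,0.64,0.08,exact,0
30,RPE1,4.89,1.97,exact,0
31,HCT116,1.03,0.13,exact,0
31,MCF7,1.44,0.19,exact,0
31,A431,1.24,0.14,exact,0
31,RPE1,7.50,1.75,exact,0
32,HCT116,1.04,0.11,exact,0
32,MCF7,2.35,0.23,exact,0
32,A431,1.31,0.09,exact,0
32,RPE1,12.07,1.76,exact,0
33,HCT116,1.13,0.19,exact,0
33,MCF7,2.14,0.26,exact,0
33,A431,1.45,0.12,exact,0
33,RPE1,11.41,1.68,exact,0
34,HCT116,0.56,0.04,exact,0
34,MCF7,2.34,0.29,exact,0
34,A431,1.27,0.09,exact,0
34,RPE1,17.50,2.16,exact,0
35,HCT116,0.56,0.06,exact,0
35,MCF7,1.36,0.17,exact,0
35,A431,1.20,0.14,exact,0
35,RPE1,8.26,2.33,exact,0
36,HCT116,0.62,0.05,exact,0
36,MCF7,1.71,0.12,exact,0
36,A431,1.31,0.08,exact,0
36,RPE1,9.46,1.86,exact,0
37,HCT116,0.57,0.07,exact,0
37,MCF7,2.32,0.30,exact,0
37,A431,1.18,0.11,exact,0
37,RPE1,9.78,1.53,exact,0
38,HCT116,0.56,0.03,exact,0
38,MCF7,2.16,0.15,exact,0
38,A431,1.33,0.17,exact,0
38,RPE1,10.87,1.42,exact,0
39,HCT116,1.44,0.17,exact,0
39,MCF7,3.96,0.29,exact,0
39,A431,2.57,0.15,exact,0
39,RPE1,50.00,3.16,greater_than,0
40,HCT116,2.73,0.20,exact,0
40,MCF7,5.10,0.30,exact,0
40,A431,4.90,0.34,exact,0
40,RPE1,50.00,2.96,greater_than,0
41,HCT116,2.26,0.23,exact,0
41,MCF7,4.58,0.28,exact,0
41,A431,2.64,0.27,exact,0
41,RPE1,18.91,1.33,exact,0
42,HCT116,22.98,1.82,exact,0
42,MCF7,4.90,0.26,exact,0
42,A431,8.75,0.40,exact,0
42,RPE1,46.96,2.17,exact,0
43,HCT116,1.23,0.15,exact,0
43,MCF7,3.96,0.23,exact,0
43,A431,2.72,0.20,exact,0
43,RPE1,50.00,3.43,greater_than,0
44,HCT116,1.11,0.09,exact,0
44,MCF7,4.17,0.27,exact,0
44,A431,2.85,0.16,exact,0
44,RPE1,50.00,2.76,greater_than,0
45,HCT116,1.38,0.15,exact,0
45,MCF7,5.85,0.31,exact,0
45,A431,11.35,1.10,exact,0
45,RPE1,50.00,3.76,greater_than,0
46,HCT116,1.50,0.14,exact,0
46,MCF7,5.73,0.33,exact,0
46,A431,8.83,1.26,exact,0
46,RPE1,47.72,3.05,exact,0
47,HCT116,1.29,0.19,exact,0
47,MCF7,4.89,0.25,exact,0
47,A431,7.98,1.34,exact,0
47,RPE1,50.00,3.99,greater_than,0
48,HCT116,50.00,1.01,greater_than,0
48,MCF7,33.72,1.38,exact,0
48,A431,50.00,3.65,greater_than,0
48,RPE1,50.00,4.16,greater_than,0
49,HCT116,40.83,2.61,exact,0
49,MCF7,24.68,1.99,exact,0
49,A431,50.00,2.08,greater_than,0
49,RPE1,50.00,4.22,greater_than,0
50,HCT116,20.09,2.44,exact,0
50,MCF7,21.67,2.78,exact,0
50,A431,40.63,2.88,exact,0
50,RPE1,47.39,2.66,exact,0
51,HCT116,50.00,2.90,greater_than,0
51,MCF7,50.00,3.01,greater_than,0
51,A431,50.00,2.38,greater_than,0
51,RPE1,50.00,2.34,greater_than,0
5-FU,HCT116,20.43,1.99,exact,1
5-FU,MCF7,3.15,0.44,exact,1
5-FU,A431,23.44,2.09,exact,1
curcumin,HCT116,38.25,2.36,exact,1
curcumin,MCF7,16.00,2.04,exact,1
27,TopoIIa,33.64,1.30,exact,0
29,TopoIIa,28.97,1.39,exact,0
30,TopoIIa,41.79,2.42,exact,0
34,TopoIIa,30.69,1.32,exact,0
35,TopoIIa,26.39,1.61,exact,0
36,TopoIIa,23.04,1.37,exact,0
37,TopoIIa,27.23,1.72,exact,0
38,TopoIIa,35.01,2.08,exact,0
39,TopoIIa,41.30,1.60,exact,0
40,TopoIIa,40.35,1.56,exact,0
41,TopoIIa,50.17,1.94,exact,0
42,TopoIIa,31.49,1.22,exact,0
43,TopoIIa,28.30,1.09,exact,0
44,TopoIIa,46.18,1.79,exact,0
45,TopoIIa,39.31,1.52,exact,0
46,TopoIIa,56.23,2.18,exact,0
47,TopoIIa,33.01,1.28,exact,0
methotrexate,TopoIIa,23.25,1.31,exact,1
combretastatin-A4,TopoIIa,22.02,0.85,exact,1
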