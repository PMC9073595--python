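compound_id,assay,value,operator
24,HCT116,15.40,exact
24,MCF7,9.09,exact
24,A431,6.68,exact
25,HCT116,21.43,exact
25,MCF7,10.56,exact
25,A431,8.79,exact
26,HCT116,12.39,exact
26,MCF7,7.15,exact
26,A431,6.26,exact
27,HCT116,31.06,less_than
27,MCF7,16.95,less_than
27,A431,19.53,less_than
28,HCT116,9.13,exact
28,MCF7,4.64,exact
28,A431,4.64,exact
29,HCT116,13.81,exact
29,MCF7,7.27,exact
29,A431,7.50,exact
30,HCT116,8.43,exact
30,MCF7,4.33,exact
30,A431,7.64,exact
31,HCT116,7.28,exact
31,MCF7,5.21,exact
31,A431,6.05,exact
32,HCT116,11.61,exact
32,MCF7,5.14,exact
32,A431,9.21,exact
33,HCT116,10.10,exact
33,MCF7,5.33,exact
33,A431,7.87,exact
34,HCT116,31.25,exact
34,MCF7,7.48,exact
34,A431,13.78,exact
35,HCT116,14.75,exact
35,MCF7,6.07,exact
35,A431,6.88,exact
36,HCT116,15.26,exact
36,MCF7,5.53,exact
36,A431,7.22,exact
37,HCT116,17.16,exact
37,MCF7,4.22,exact
37,A431,8.29,exact
38,HCT116,19.41,exact
38,MCF7,5.03,exact
38,A431,8.17,exact
39,HCT116,34.72,less_than
39,MCF7,12.63,less_than
39,A431,19.46,less_than
40,HCT116,18.32,less_than
40,MCF7,9.80,less_than
40,A431,10.20,less_than
41,HCT116,8.37,exact
41,MCF7,4.13,exact
41,A431,7.16,exact
42,HCT116,2.04,exact
42,MCF7,9.58,exact
42,A431,5.37,exact
43,HCT116,40.65,less_than
43,MCF7,12.63,less_than
43,A431,18.38,less_than
44,HCT116,45.05,less_than
44,MCF7,11.99,less_than
44,A431,17.54,less_than
45,HCT116,36.23,less_than
45,MCF7,8.55,less_than
45,A431,4.41,less_than
46,HCT116,31.81,exact
46,MCF7,8.33,exact
46,A431,5.40,exact
47,HCT116,38.76,less_than
47,MCF7,10.22,less_than
47,A431,6.27,less_than
48,HCT116,,undefined
48,MCF7,1.48,less_than
48,A431,,undefined
49,HCT116,1.22,less_than
49,MCF7,2.03,less_than
49,A431,,undefined
50,HCT116,2.36,exact
50,MCF7,2.19,exact
50,A431,1.17,exact
51,HCT116,,undefined
51,MCF7,,undefined
51,A431,,undefined
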