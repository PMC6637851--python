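id,experimental_pKi,predicted_pKi,split
1,9.16,9.37,train
2,7.60,7.54,train
3,7.41,7.49,train
4,6.99,6.96,train
5,7.70,7.62,train
6,7.67,7.44,train
7,8.85,8.73,train
8,6.00,6.79,test
9,6.09,6.23,train
10,6.00,6.14,train
11,7.33,7.11,train
12,8.71,7.99,test
13,7.72,7.65,train
14,8.64,8.41,train
15,8.99,9.05,train
16,8.22,8.10,train
17,8.62,8.26,train
18,8.10,8.09,train
19,8.20,8.29,train
20,7.86,8.22,train
21,7.04,7.06,train
22,8.28,8.11,train
23,8.27,8.96,test
24,8.24,8.30,train
25,8.64,8.52,train
26,7.98,8.01,train
27,9.01,8.79,train
28,9.07,9.22,train
29,6.34,6.23,test
30,7.85,7.67,train
31,7.04,7.10,train
32,8.36,8.62,train
33,8.89,8.99,train
34,7.64,7.65,test
35,8.15,8.20,train
36,8.97,8.56,test
37,8.38,8.28,test
38,8.11,7.40,test
39,8.02,8.04,train
40,7.94,7.83,train
41,6.00,6.38,train
42,6.00,5.98,train
43,6.00,7.29,test
44,6.00,6.03,train
45,6.00,6.16,train
46,6.00,5.78,train
47,6.00,6.36,test
48,6.00,5.89,train
49,6.00,5.75,train
50,7.41,7.52,train
51,8.33,8.37,train
52,6.69,6.81,train
53,7.20,7.40,train
54,7.29,7.44,test
55,7.60,7.90,train
56,8.82,8.57,train
57,8.22,8.29,train
58,8.16,8.14,train
59,8.27,8.20,train
60,6.94,6.91,train
61,7.70,7.68,train
62,8.46,8.37,train
63,7.12,7.20,train
64,6.62,6.75,train
65,7.44,6.42,test
66,8.54,8.56,train
67,6.86,7.25,test
68,6.37,6.35,train
69,7.34,7.37,train
70,8.54,8.62,test
71,8.52,8.45,train
72,7.07,6.56,test
73,8.00,8.01,train
74,7.96,7.92,train
75,7.57,7.73,train
76,7.40,7.45,train
77,7.15,7.09,train
78,7.21,7.18,train
79,7.46,7.42,train
80,7.89,7.19,test
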