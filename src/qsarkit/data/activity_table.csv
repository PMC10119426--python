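# VEGFR3 kinase inhibition table: 50 compounds, IC50 in micromolar.
# test_2d marks the 10-compound hold-out set of the 2D-QSAR experiment.
# test_3d marks the 3D-QSAR hold-out; the source annotation (an underline)
# does not survive text extraction, so it mirrors test_2d as a documented
# stand-in (see package docs).
compound_id,ic50_uM,test_2d,test_3d
1,15.41,0,0
2,20.35,1,1
3,17.85,0,0
4,18.98,0,0
5,18.0,1,1
6,6.41,1,1
7,29.87,0,0
8,8.05,0,0
9,18.38,0,0
10,7.55,0,0
11,8.65,1,1
12,23.65,0,0
13,20.97,0,0
14,0.76,0,0
15,27.74,1,1
16,9.27,0,0
17,16.02,1,1
18,24.11,0,0
19,10.42,1,1
20,19.11,0,0
21,28.17,1,1
22,34.12,0,0
23,3.01,0,0
24,3.18,1,1
25,4.20,0,0
26,3.33,0,0
27,3.56,0,0
28,40.42,0,0
29,2.88,0,0
30,6.18,0,0
31,5.9,0,0
32,7.33,0,0
33,8.13,0,0
34,11.48,0,0
35,8.33,0,0
36,7.59,0,0
37,20.92,0,0
38,3.93,0,0
39,5.44,0,0
40,4.60,1,1
41,10.27,0,0
42,13.23,0,0
43,23.23,0,0
44,11.43,0,0
45,2.22,0,0
46,8.43,0,0
47,9.09,0,0
48,4.20,0,0
49,5.39,0,0
50,4.42,0,0
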