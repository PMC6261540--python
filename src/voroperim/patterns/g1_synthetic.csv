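index,x_deg,y_deg,blind_spot
0,2.1,2.1,0
1,-2.1,2.1,0
2,-2.1,-2.1,0
3,2.1,-2.1,0
4,6.0,0.0,0
5,4.2,4.2,0
6,0.0,6.0,0
7,-4.2,4.2,0
8,-6.0,0.0,0
9,-4.2,-4.2,0
10,-0.0,-6.0,0
11,4.2,-4.2,0
12,9.2,3.8,0
13,3.8,9.2,0
14,-3.8,9.2,0
15,-9.2,3.8,0
16,-9.2,-3.8,0
17,-3.8,-9.2,0
18,3.8,-9.2,0
19,9.2,-3.8,0
20,14.0,0.0,0
21,9.9,9.9,0
22,0.0,14.0,0
23,-9.9,9.9,0
24,-14.0,0.0,0
25,-9.9,-9.9,0
26,-0.0,-14.0,0
27,9.9,-9.9,0
28,16.6,6.9,0
29,6.9,16.6,0
30,-6.9,16.6,0
31,-16.6,6.9,0
32,-16.6,-6.9,0
33,-6.9,-16.6,0
34,6.9,-16.6,0
35,16.6,-6.9,0
36,22.0,0.0,0
37,15.6,15.6,0
38,0.0,22.0,0
39,-15.6,15.6,0
40,-22.0,0.0,0
41,-15.6,-15.6,0
42,-0.0,-22.0,0
43,15.6,-15.6,0
44,24.0,9.9,0
45,9.9,24.0,0
46,-9.9,24.0,0
47,-24.0,9.9,0
48,-24.0,-9.9,0
49,-9.9,-24.0,0
50,9.9,-24.0,0
51,24.0,-9.9,0
52,20.5,20.5,0
53,0.0,29.0,0
54,-20.5,20.5,0
55,-29.0,0.0,0
56,-20.5,-20.5,0
57,-0.0,-29.0,0
58,20.5,-20.5,0
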