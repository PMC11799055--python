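no,mri_pdff_percent,grade_group,findings_count
1,1.9,G0,0
2,2.3,G0,4
3,2.4,G0,0
4,2.7,G0,0
5,4.2,G0,3
6,4.2,G0,1
7,4.5,G0,1
8,4.6,G0,1
9,4.7,G0,4
10,5.0,G0,4
11,5.4,G1,5
12,5.4,G1,4
13,6.2,G1,5
14,6.7,G1,3
15,7.5,G1,3
16,8.0,G1,5
17,8.4,G1,0
18,8.5,G1,5
19,8.9,G1,2
20,9.4,G1,4
21,11.9,G2-3,5
22,12.7,G2-3,4
23,13.5,G2-3,2
24,16.6,G2-3,4
25,18.7,G2-3,4
26,21.6,G2-3,4
27,22.0,G2-3,5
28,23.8,G2-3,4
29,25.9,G2-3,5
30,32.1,G2-3,2
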