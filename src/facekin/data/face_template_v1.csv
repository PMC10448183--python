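point,X,Y,Z
17,-62,-12,-8
18,-52,-18,-6
19,-40,-21,-4
20,-28,-19,-3
21,-16,-15,-3
22,16,-15,-3
23,28,-19,-3
24,40,-21,-4
25,52,-18,-6
26,62,-12,-8
27,0,0,-10
28,0,12,-14
29,0,24,-19
30,0,36,-26
31,-14,46,-14
32,-7,50,-17
33,0,52,-19
34,7,50,-17
35,14,46,-14
36,-52,0,-2
37,-43,-5,-5
38,-33,-5,-5
39,-25,0,-3
40,-33,5,-4
41,-43,5,-4
42,25,0,-3
43,33,-5,-5
44,43,-5,-5
45,52,0,-2
46,43,5,-4
47,33,5,-4
48,-30,75,-12
49,-20,68,-17
50,-9,65,-20
51,0,66,-21
52,9,65,-20
53,20,68,-17
54,30,75,-12
55,20,84,-16
56,9,88,-19
57,0,89,-20
58,-9,88,-19
59,-20,84,-16
60,-25,75,-13
61,-9,73,-17
62,0,73.5,-18
63,9,73,-17
64,25,75,-13
65,9,77,-17
66,0,77.5,-18
67,-9,77,-17
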