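gene	direction
37755	up
98906	up
66957	up
16531	up
67793	up
37181	up
87226	up
8945	up
87290	up
10180	up
52580	up
24764	up
59305	up
49832	up
60441	up
30642	up
9717	up
84183	up
48967	up
94615	up
17977	up
15997	up
24908	up
49788	up
74348	up
53368	up
69091	up
81584	up
60849	up
23703	up
36069	up
54460	up
60474	up
25593	up
73810	up
15040	up
36523	up
44687	up
89169	up
38460	up
55073	up
10213	up
64388	up
13628	up
50189	up
18077	up
25109	up
82651	up
79988	up
67770	up
4447	up
83434	down
84181	down
1225	down
54538	down
2345	down
40403	down
55872	down
23017	down
39411	down
68228	down
24890	down
93883	down
69400	down
91912	down
48404	down
59997	down
71009	down
35937	down
51658	down
7167	down
89381	down
2567	down
19616	down
60854	down
41930	down
43441	down
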