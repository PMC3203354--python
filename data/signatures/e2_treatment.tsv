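gene	direction
74828	up
30141	up
10458	up
44942	up
8095	up
52151	up
39647	up
29606	up
93926	up
31120	up
94079	up
16712	up
30076	up
86564	up
75604	up
62943	up
20759	up
31648	up
10660	up
21765	up
23144	up
54955	up
84971	up
30014	up
24551	up
37931	up
44250	up
4665	up
58399	up
98585	up
59255	up
64514	up
96939	up
90562	up
61737	down
33505	down
65560	down
48773	down
18725	down
64884	down
99220	down
16040	down
38288	down
4496	down
38951	down
1014	down
95808	down
33737	down
60130	down
35116	down
65980	down
52977	down
11680	down
3264	down
47277	down
59699	down
75173	down
1608	down
88621	down
96191	down
65480	down
25935	down
36684	down
51405	down
84369	down
44827	down
71549	down
73451	down
52257	down
82420	down
66054	down
30967	down
91252	down
55994	down
3863	down
34735	down
98039	down
99621	down
82558	down
65591	down
43679	down
68458	down
83347	down
88161	down
54482	down
31202	down
64401	down
98087	down
17103	down
93142	down
31277	down
96591	down
56107	down
80290	down
9692	down
95684	down
70234	down
98973	down
6027	down
5388	down
3649	down
99111	down
94689	down
4796	down
16850	down
14813	down
32174	down
6652	down
79054	down
9432	down
56355	down
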