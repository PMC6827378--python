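label	base	element	partner
1	G	acceptor_stem	72
2	G	acceptor_stem	71
3	C	acceptor_stem	70
4	A	acceptor_stem	69
5	C	acceptor_stem	68
6	G	acceptor_stem	67
7	G	acceptor_stem	66
8	U	linker	-
9	G	linker	-
10	G	D_stem	25
11	C	D_stem	24
12	C	D_stem	23
13	C	D_stem	22
14	A	D_loop	-
15	G	D_loop	-
16	C	D_loop	-
17	G	D_loop	-
18	G	D_loop	-
19	U	D_loop	-
20	U	D_loop	-
20a	A	D_loop	-
20b	A	D_loop	-
21	A	D_loop	-
22	G	D_stem	13
23	G	D_stem	12
24	G	D_stem	11
25	C	D_stem	10
26	G	linker	-
27	C	anticodon_stem	43
28	G	anticodon_stem	42
29	A	anticodon_stem	41
30	G	anticodon_stem	40
31	A	anticodon_stem	39
32	C	anticodon_loop	-
33	U	anticodon_loop	-
34	U	anticodon_loop	-
35	G	anticodon_loop	-
36	G	anticodon_loop	-
37	A	anticodon_loop	-
38	A	anticodon_loop	-
39	U	anticodon_stem	31
40	C	anticodon_stem	30
41	U	anticodon_stem	29
42	C	anticodon_stem	28
43	G	anticodon_stem	27
44	U	linker	-
45	G	variable_arm_stem	e21
e11	G	variable_arm_stem	e22
e12	C	variable_arm_stem	e23
e13	U	variable_arm_loop	-
e14	U	variable_arm_loop	-
e15	C	variable_arm_loop	-
e16	A	variable_arm_loop	-
e23	G	variable_arm_stem	e12
e22	C	variable_arm_stem	e11
e21	C	variable_arm_stem	45
48	C	linker	-
49	G	T_stem	65
50	G	T_stem	64
51	U	T_stem	63
52	G	T_stem	62
53	G	T_stem	61
54	U	T_loop	-
55	U	T_loop	-
56	C	T_loop	-
57	G	T_loop	-
58	A	T_loop	-
59	A	T_loop	-
60	U	T_loop	-
61	C	T_stem	53
62	C	T_stem	52
63	G	T_stem	51
64	C	T_stem	50
65	C	T_stem	49
66	C	acceptor_stem	7
67	C	acceptor_stem	6
68	G	acceptor_stem	5
69	U	acceptor_stem	4
70	G	acceptor_stem	3
71	C	acceptor_stem	2
72	C	acceptor_stem	1
73	G	linker	-
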