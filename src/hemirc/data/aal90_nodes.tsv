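region_id	region_name	hemisphere	homologue_id
0	PreCG	L	45
1	SFGdor	L	46
2	ORBsup	L	47
3	MFG	L	48
4	ORBmid	L	49
5	IFGoperc	L	50
6	IFGtriang	L	51
7	ORBinf	L	52
8	ROL	L	53
9	SMA	L	54
10	OLF	L	55
11	SFGmed	L	56
12	ORBsupmed	L	57
13	REC	L	58
14	INS	L	59
15	ACG	L	60
16	DCG	L	61
17	PCG	L	62
18	HIP	L	63
19	PHG	L	64
20	AMYG	L	65
21	CAL	L	66
22	CUN	L	67
23	LING	L	68
24	SOG	L	69
25	MOG	L	70
26	IOG	L	71
27	FFG	L	72
28	PoCG	L	73
29	SPG	L	74
30	IPL	L	75
31	SMG	L	76
32	ANG	L	77
33	PCUN	L	78
34	PCL	L	79
35	CAU	L	80
36	PUT	L	81
37	PAL	L	82
38	THA	L	83
39	HES	L	84
40	STG	L	85
41	TPOsup	L	86
42	MTG	L	87
43	TPOmid	L	88
44	ITG	L	89
45	PreCG	R	0
46	SFGdor	R	1
47	ORBsup	R	2
48	MFG	R	3
49	ORBmid	R	4
50	IFGoperc	R	5
51	IFGtriang	R	6
52	ORBinf	R	7
53	ROL	R	8
54	SMA	R	9
55	OLF	R	10
56	SFGmed	R	11
57	ORBsupmed	R	12
58	REC	R	13
59	INS	R	14
60	ACG	R	15
61	DCG	R	16
62	PCG	R	17
63	HIP	R	18
64	PHG	R	19
65	AMYG	R	20
66	CAL	R	21
67	CUN	R	22
68	LING	R	23
69	SOG	R	24
70	MOG	R	25
71	IOG	R	26
72	FFG	R	27
73	PoCG	R	28
74	SPG	R	29
75	IPL	R	30
76	SMG	R	31
77	ANG	R	32
78	PCUN	R	33
79	PCL	R	34
80	CAU	R	35
81	PUT	R	36
82	PAL	R	37
83	THA	R	38
84	HES	R	39
85	STG	R	40
86	TPOsup	R	41
87	MTG	R	42
88	TPOmid	R	43
89	ITG	R	44
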