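scheme	chain_type	position	aa
imgt	heavy	1	E
imgt	heavy	2	V
imgt	heavy	3	Q
imgt	heavy	4	L
imgt	heavy	5	L
imgt	heavy	6	E
imgt	heavy	7	S
imgt	heavy	8	G
imgt	heavy	9	G
imgt	heavy	11	G
imgt	heavy	12	L
imgt	heavy	13	V
imgt	heavy	14	Q
imgt	heavy	15	P
imgt	heavy	16	G
imgt	heavy	17	G
imgt	heavy	18	S
imgt	heavy	19	L
imgt	heavy	20	R
imgt	heavy	21	L
imgt	heavy	22	S
imgt	heavy	23	C
imgt	heavy	24	A
imgt	heavy	25	A
imgt	heavy	26	S
imgt	heavy	27	G
imgt	heavy	28	F
imgt	heavy	29	T
imgt	heavy	30	F
imgt	heavy	35	S
imgt	heavy	36	S
imgt	heavy	37	Y
imgt	heavy	38	A
imgt	heavy	39	M
imgt	heavy	40	S
imgt	heavy	41	W
imgt	heavy	42	V
imgt	heavy	43	R
imgt	heavy	44	Q
imgt	heavy	45	A
imgt	heavy	46	P
imgt	heavy	47	G
imgt	heavy	48	K
imgt	heavy	49	G
imgt	heavy	50	L
imgt	heavy	51	E
imgt	heavy	52	W
imgt	heavy	53	V
imgt	heavy	54	S
imgt	heavy	55	A
imgt	heavy	56	I
imgt	heavy	57	S
imgt	heavy	58	G
imgt	heavy	59	S
imgt	heavy	62	G
imgt	heavy	63	G
imgt	heavy	64	S
imgt	heavy	65	T
imgt	heavy	66	Y
imgt	heavy	67	Y
imgt	heavy	68	A
imgt	heavy	69	D
imgt	heavy	70	S
imgt	heavy	71	V
imgt	heavy	72	K
imgt	heavy	74	G
imgt	heavy	75	R
imgt	heavy	76	F
imgt	heavy	77	T
imgt	heavy	78	I
imgt	heavy	79	S
imgt	heavy	80	R
imgt	heavy	81	D
imgt	heavy	82	N
imgt	heavy	83	S
imgt	heavy	84	K
imgt	heavy	85	N
imgt	heavy	86	T
imgt	heavy	87	L
imgt	heavy	88	Y
imgt	heavy	89	L
imgt	heavy	90	Q
imgt	heavy	91	M
imgt	heavy	92	N
imgt	heavy	93	S
imgt	heavy	94	L
imgt	heavy	95	R
imgt	heavy	96	A
imgt	heavy	97	E
imgt	heavy	98	D
imgt	heavy	99	T
imgt	heavy	100	A
imgt	heavy	101	V
imgt	heavy	102	Y
imgt	heavy	103	Y
imgt	heavy	104	C
imgt	heavy	105	A
imgt	heavy	106	K
imgt	heavy	107	D
imgt	heavy	108	L
imgt	heavy	109	G
imgt	heavy	114	Y
imgt	heavy	115	F
imgt	heavy	116	D
imgt	heavy	117	Y
imgt	heavy	118	W
imgt	heavy	119	G
imgt	heavy	120	Q
imgt	heavy	121	G
imgt	heavy	122	T
imgt	heavy	123	L
imgt	heavy	124	V
imgt	heavy	125	T
imgt	heavy	126	V
imgt	heavy	127	S
imgt	heavy	128	S
kabat	heavy	1	E
kabat	heavy	2	V
kabat	heavy	3	Q
kabat	heavy	4	L
kabat	heavy	5	L
kabat	heavy	6	E
kabat	heavy	7	S
kabat	heavy	8	G
kabat	heavy	9	G
kabat	heavy	10	G
kabat	heavy	11	L
kabat	heavy	12	V
kabat	heavy	13	Q
kabat	heavy	14	P
kabat	heavy	15	G
kabat	heavy	16	G
kabat	heavy	17	S
kabat	heavy	18	L
kabat	heavy	19	R
kabat	heavy	20	L
kabat	heavy	21	S
kabat	heavy	22	C
kabat	heavy	23	A
kabat	heavy	24	A
kabat	heavy	25	S
kabat	heavy	26	G
kabat	heavy	27	F
kabat	heavy	28	T
kabat	heavy	29	F
kabat	heavy	30	S
kabat	heavy	31	S
kabat	heavy	32	Y
kabat	heavy	33	A
kabat	heavy	34	M
kabat	heavy	35	S
kabat	heavy	36	W
kabat	heavy	37	V
kabat	heavy	38	R
kabat	heavy	39	Q
kabat	heavy	40	A
kabat	heavy	41	P
kabat	heavy	42	G
kabat	heavy	43	K
kabat	heavy	44	G
kabat	heavy	45	L
kabat	heavy	46	E
kabat	heavy	47	W
kabat	heavy	48	V
kabat	heavy	49	S
kabat	heavy	50	A
kabat	heavy	51	I
kabat	heavy	52	S
kabat	heavy	53	G
kabat	heavy	54	S
kabat	heavy	55	G
kabat	heavy	56	G
kabat	heavy	57	S
kabat	heavy	58	T
kabat	heavy	59	Y
kabat	heavy	60	Y
kabat	heavy	61	A
kabat	heavy	62	D
kabat	heavy	63	S
kabat	heavy	64	V
kabat	heavy	65	K
kabat	heavy	66	G
kabat	heavy	67	R
kabat	heavy	68	F
kabat	heavy	69	T
kabat	heavy	70	I
kabat	heavy	71	S
kabat	heavy	72	R
kabat	heavy	73	D
kabat	heavy	74	N
kabat	heavy	75	S
kabat	heavy	76	K
kabat	heavy	77	N
kabat	heavy	78	T
kabat	heavy	79	L
kabat	heavy	80	Y
kabat	heavy	81	L
kabat	heavy	82	Q
kabat	heavy	83	M
kabat	heavy	84	N
kabat	heavy	85	S
kabat	heavy	86	L
kabat	heavy	87	R
kabat	heavy	88	A
kabat	heavy	89	E
kabat	heavy	90	D
kabat	heavy	91	T
kabat	heavy	92	A
kabat	heavy	93	V
kabat	heavy	94	Y
kabat	heavy	95	Y
kabat	heavy	96	C
kabat	heavy	97	A
kabat	heavy	98	K
kabat	heavy	99	D
kabat	heavy	100	L
kabat	heavy	101	G
kabat	heavy	102	Y
kabat	heavy	103	F
kabat	heavy	104	D
kabat	heavy	105	Y
kabat	heavy	106	W
kabat	heavy	107	G
kabat	heavy	108	Q
kabat	heavy	109	G
kabat	heavy	110	T
kabat	heavy	111	L
kabat	heavy	112	V
kabat	heavy	113	T
kabat	heavy	114	V
kabat	heavy	115	S
kabat	heavy	116	S
imgt	kappa	1	E
imgt	kappa	2	I
imgt	kappa	3	V
imgt	kappa	4	L
imgt	kappa	5	T
imgt	kappa	6	Q
imgt	kappa	7	S
imgt	kappa	8	P
imgt	kappa	9	G
imgt	kappa	10	T
imgt	kappa	11	L
imgt	kappa	12	S
imgt	kappa	13	L
imgt	kappa	14	S
imgt	kappa	15	P
imgt	kappa	16	G
imgt	kappa	17	E
imgt	kappa	18	R
imgt	kappa	19	A
imgt	kappa	20	T
imgt	kappa	21	L
imgt	kappa	22	S
imgt	kappa	23	C
imgt	kappa	24	R
imgt	kappa	25	A
imgt	kappa	26	S
imgt	kappa	27	Q
imgt	kappa	28	S
imgt	kappa	29	V
imgt	kappa	30	S
imgt	kappa	36	S
imgt	kappa	37	S
imgt	kappa	38	Y
imgt	kappa	39	L
imgt	kappa	40	A
imgt	kappa	41	W
imgt	kappa	42	Y
imgt	kappa	43	Q
imgt	kappa	44	Q
imgt	kappa	45	K
imgt	kappa	46	P
imgt	kappa	47	G
imgt	kappa	48	Q
imgt	kappa	49	A
imgt	kappa	50	P
imgt	kappa	51	R
imgt	kappa	52	L
imgt	kappa	53	L
imgt	kappa	54	I
imgt	kappa	55	Y
imgt	kappa	56	G
imgt	kappa	57	A
imgt	kappa	65	S
imgt	kappa	66	S
imgt	kappa	67	R
imgt	kappa	68	A
imgt	kappa	69	T
imgt	kappa	70	G
imgt	kappa	71	I
imgt	kappa	72	P
imgt	kappa	76	D
imgt	kappa	77	R
imgt	kappa	78	F
imgt	kappa	79	S
imgt	kappa	80	G
imgt	kappa	81	S
imgt	kappa	82	G
imgt	kappa	83	S
imgt	kappa	84	G
imgt	kappa	85	T
imgt	kappa	86	D
imgt	kappa	87	F
imgt	kappa	88	T
imgt	kappa	89	L
imgt	kappa	90	T
imgt	kappa	91	I
imgt	kappa	92	S
imgt	kappa	93	R
imgt	kappa	94	L
imgt	kappa	95	E
imgt	kappa	96	P
imgt	kappa	97	E
imgt	kappa	98	D
imgt	kappa	99	F
imgt	kappa	100	A
imgt	kappa	101	V
imgt	kappa	102	Y
imgt	kappa	103	Y
imgt	kappa	104	C
imgt	kappa	105	Q
imgt	kappa	106	Q
imgt	kappa	107	Y
imgt	kappa	108	G
imgt	kappa	109	S
imgt	kappa	114	S
imgt	kappa	115	P
imgt	kappa	116	W
imgt	kappa	117	T
imgt	kappa	118	F
imgt	kappa	119	G
imgt	kappa	120	Q
imgt	kappa	121	G
imgt	kappa	122	T
imgt	kappa	123	K
imgt	kappa	124	V
imgt	kappa	125	E
imgt	kappa	126	I
imgt	kappa	127	K
kabat	kappa	1	E
kabat	kappa	2	I
kabat	kappa	3	V
kabat	kappa	4	L
kabat	kappa	5	T
kabat	kappa	6	Q
kabat	kappa	7	S
kabat	kappa	8	P
kabat	kappa	9	G
kabat	kappa	10	T
kabat	kappa	11	L
kabat	kappa	12	S
kabat	kappa	13	L
kabat	kappa	14	S
kabat	kappa	15	P
kabat	kappa	16	G
kabat	kappa	17	E
kabat	kappa	18	R
kabat	kappa	19	A
kabat	kappa	20	T
kabat	kappa	21	L
kabat	kappa	22	S
kabat	kappa	23	C
kabat	kappa	24	R
kabat	kappa	25	A
kabat	kappa	26	S
kabat	kappa	27	Q
kabat	kappa	28	S
kabat	kappa	29	V
kabat	kappa	30	S
kabat	kappa	31	S
kabat	kappa	32	S
kabat	kappa	33	Y
kabat	kappa	34	L
kabat	kappa	35	A
kabat	kappa	36	W
kabat	kappa	37	Y
kabat	kappa	38	Q
kabat	kappa	39	Q
kabat	kappa	40	K
kabat	kappa	41	P
kabat	kappa	42	G
kabat	kappa	43	Q
kabat	kappa	44	A
kabat	kappa	45	P
kabat	kappa	46	R
kabat	kappa	47	L
kabat	kappa	48	L
kabat	kappa	49	I
kabat	kappa	50	Y
kabat	kappa	51	G
kabat	kappa	52	A
kabat	kappa	53	S
kabat	kappa	54	S
kabat	kappa	55	R
kabat	kappa	56	A
kabat	kappa	57	T
kabat	kappa	58	G
kabat	kappa	59	I
kabat	kappa	60	P
kabat	kappa	61	D
kabat	kappa	62	R
kabat	kappa	63	F
kabat	kappa	64	S
kabat	kappa	65	G
kabat	kappa	66	S
kabat	kappa	67	G
kabat	kappa	68	S
kabat	kappa	69	G
kabat	kappa	70	T
kabat	kappa	71	D
kabat	kappa	72	F
kabat	kappa	73	T
kabat	kappa	74	L
kabat	kappa	75	T
kabat	kappa	76	I
kabat	kappa	77	S
kabat	kappa	78	R
kabat	kappa	79	L
kabat	kappa	80	E
kabat	kappa	81	P
kabat	kappa	82	E
kabat	kappa	83	D
kabat	kappa	84	F
kabat	kappa	85	A
kabat	kappa	86	V
kabat	kappa	87	Y
kabat	kappa	88	Y
kabat	kappa	89	C
kabat	kappa	90	Q
kabat	kappa	91	Q
kabat	kappa	92	Y
kabat	kappa	93	G
kabat	kappa	94	S
kabat	kappa	95	S
kabat	kappa	96	P
kabat	kappa	97	W
kabat	kappa	98	T
kabat	kappa	99	F
kabat	kappa	100	G
kabat	kappa	101	Q
kabat	kappa	102	G
kabat	kappa	103	T
kabat	kappa	104	K
kabat	kappa	105	V
kabat	kappa	106	E
kabat	kappa	107	I
kabat	kappa	108	K
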