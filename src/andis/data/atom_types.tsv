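# andis-atom-types/1
# residue	atom	index	frame_neighbor_candidates
ALA	N	0	-C,CA,C,CB
ALA	CA	1	N,C,CB,O
ALA	C	2	CA,O,+N,N,CB
ALA	O	3	C,CA
ALA	CB	4	CA,N,C
ARG	N	5	-C,CA,C,CB
ARG	CA	6	N,C,CB,O,CG
ARG	C	7	CA,O,+N,N,CB
ARG	O	8	C,CA
ARG	CB	9	CA,CG,N,C,CD
ARG	CG	10	CB,CD,CA,NE
ARG	CD	11	CG,NE,CB,CZ
ARG	NE	12	CD,CZ,CG,NH1,NH2
ARG	CZ	13	NE,NH1,NH2,CD
ARG	NH1	14	CZ,NE,NH2
ARG	NH2	15	CZ,NE,NH1
ASN	N	16	-C,CA,C,CB
ASN	CA	17	N,C,CB,O,CG
ASN	C	18	CA,O,+N,N,CB
ASN	O	19	C,CA
ASN	CB	20	CA,CG,N,C,OD1,ND2
ASN	CG	21	CB,OD1,ND2,CA
ASN	OD1	22	CG,CB,ND2
ASN	ND2	23	CG,CB,OD1
ASP	N	24	-C,CA,C,CB
ASP	CA	25	N,C,CB,O,CG
ASP	C	26	CA,O,+N,N,CB
ASP	O	27	C,CA
ASP	CB	28	CA,CG,N,C,OD1,OD2
ASP	CG	29	CB,OD1,OD2,CA
ASP	OD1	30	CG,CB,OD2
ASP	OD2	31	CG,CB,OD1
CYS	N	32	-C,CA,C,CB
CYS	CA	33	N,C,CB,O,SG
CYS	C	34	CA,O,+N,N,CB
CYS	O	35	C,CA
CYS	CB	36	CA,SG,N,C
CYS	SG	37	CB,CA
GLN	N	38	-C,CA,C,CB
GLN	CA	39	N,C,CB,O,CG
GLN	C	40	CA,O,+N,N,CB
GLN	O	41	C,CA
GLN	CB	42	CA,CG,N,C,CD
GLN	CG	43	CB,CD,CA,OE1,NE2
GLN	CD	44	CG,OE1,NE2,CB
GLN	OE1	45	CD,CG,NE2
GLN	NE2	46	CD,CG,OE1
GLU	N	47	-C,CA,C,CB
GLU	CA	48	N,C,CB,O,CG
GLU	C	49	CA,O,+N,N,CB
GLU	O	50	C,CA
GLU	CB	51	CA,CG,N,C,CD
GLU	CG	52	CB,CD,CA,OE1,OE2
GLU	CD	53	CG,OE1,OE2,CB
GLU	OE1	54	CD,CG,OE2
GLU	OE2	55	CD,CG,OE1
GLY	N	56	-C,CA,C
GLY	CA	57	N,C,O
GLY	C	58	CA,O,+N,N
GLY	O	59	C,CA
HIS	N	60	-C,CA,C,CB
HIS	CA	61	N,C,CB,O,CG
HIS	C	62	CA,O,+N,N,CB
HIS	O	63	C,CA
HIS	CB	64	CA,CG,N,C,ND1,CD2
HIS	CG	65	CB,ND1,CD2,CA,CE1,NE2
HIS	ND1	66	CG,CE1,CB,CD2,NE2
HIS	CD2	67	CG,NE2,CB,ND1,CE1
HIS	CE1	68	ND1,NE2,CG,CD2
HIS	NE2	69	CD2,CE1,CG,ND1
ILE	N	70	-C,CA,C,CB
ILE	CA	71	N,C,CB,O,CG1,CG2
ILE	C	72	CA,O,+N,N,CB
ILE	O	73	C,CA
ILE	CB	74	CA,CG1,CG2,N,C,CD1
ILE	CG1	75	CB,CD1,CA,CG2
ILE	CG2	76	CB,CA,CG1
ILE	CD1	77	CG1,CB
LEU	N	78	-C,CA,C,CB
LEU	CA	79	N,C,CB,O,CG
LEU	C	80	CA,O,+N,N,CB
LEU	O	81	C,CA
LEU	CB	82	CA,CG,N,C,CD1,CD2
LEU	CG	83	CB,CD1,CD2,CA
LEU	CD1	84	CG,CB,CD2
LEU	CD2	85	CG,CB,CD1
LYS	N	86	-C,CA,C,CB
LYS	CA	87	N,C,CB,O,CG
LYS	C	88	CA,O,+N,N,CB
LYS	O	89	C,CA
LYS	CB	90	CA,CG,N,C,CD
LYS	CG	91	CB,CD,CA,CE
LYS	CD	92	CG,CE,CB,NZ
LYS	CE	93	CD,NZ,CG
LYS	NZ	94	CE,CD
MET	N	95	-C,CA,C,CB
MET	CA	96	N,C,CB,O,CG
MET	C	97	CA,O,+N,N,CB
MET	O	98	C,CA
MET	CB	99	CA,CG,N,C,SD
MET	CG	100	CB,SD,CA,CE
MET	SD	101	CG,CE,CB
MET	CE	102	SD,CG
PHE	N	103	-C,CA,C,CB
PHE	CA	104	N,C,CB,O,CG
PHE	C	105	CA,O,+N,N,CB
PHE	O	106	C,CA
PHE	CB	107	CA,CG,N,C,CD1,CD2
PHE	CG	108	CB,CD1,CD2,CA,CE1,CE2
PHE	CD1	109	CG,CE1,CB,CD2,CZ
PHE	CD2	110	CG,CE2,CB,CD1,CZ
PHE	CE1	111	CD1,CZ,CG,CE2
PHE	CE2	112	CD2,CZ,CG,CE1
PHE	CZ	113	CE1,CE2,CD1,CD2
PRO	N	114	-C,CA,CD,C,CB,CG
PRO	CA	115	N,C,CB,CD,O,CG
PRO	C	116	CA,O,+N,N,CB
PRO	O	117	C,CA
PRO	CB	118	CA,CG,N,C,CD
PRO	CG	119	CB,CD,CA,N
PRO	CD	120	N,CG,CA,CB
SER	N	121	-C,CA,C,CB
SER	CA	122	N,C,CB,O,OG
SER	C	123	CA,O,+N,N,CB
SER	O	124	C,CA
SER	CB	125	CA,OG,N,C
SER	OG	126	CB,CA
THR	N	127	-C,CA,C,CB
THR	CA	128	N,C,CB,O,OG1,CG2
THR	C	129	CA,O,+N,N,CB
THR	O	130	C,CA
THR	CB	131	CA,OG1,CG2,N,C
THR	OG1	132	CB,CA,CG2
THR	CG2	133	CB,CA,OG1
TRP	N	134	-C,CA,C,CB
TRP	CA	135	N,C,CB,O,CG
TRP	C	136	CA,O,+N,N,CB
TRP	O	137	C,CA
TRP	CB	138	CA,CG,N,C,CD1,CD2
TRP	CG	139	CB,CD1,CD2,CA,NE1,CE2,CE3
TRP	CD1	140	CG,NE1,CB,CD2,CE2
TRP	CD2	141	CG,CE2,CE3,CB,CD1,NE1,CZ2,CZ3
TRP	NE1	142	CD1,CE2,CG,CD2,CZ2
TRP	CE2	143	CD2,NE1,CZ2,CG,CE3,CD1,CH2
TRP	CE3	144	CD2,CZ3,CG,CE2,CH2
TRP	CZ2	145	CE2,CH2,CD2,NE1,CZ3
TRP	CZ3	146	CE3,CH2,CD2,CZ2
TRP	CH2	147	CZ2,CZ3,CE2,CE3
TYR	N	148	-C,CA,C,CB
TYR	CA	149	N,C,CB,O,CG
TYR	C	150	CA,O,+N,N,CB
TYR	O	151	C,CA
TYR	CB	152	CA,CG,N,C,CD1,CD2
TYR	CG	153	CB,CD1,CD2,CA,CE1,CE2
TYR	CD1	154	CG,CE1,CB,CD2,CZ
TYR	CD2	155	CG,CE2,CB,CD1,CZ
TYR	CE1	156	CD1,CZ,CG,CE2,OH
TYR	CE2	157	CD2,CZ,CG,CE1,OH
TYR	CZ	158	CE1,CE2,OH,CD1,CD2
TYR	OH	159	CZ,CE1,CE2
VAL	N	160	-C,CA,C,CB
VAL	CA	161	N,C,CB,O,CG1,CG2
VAL	C	162	CA,O,+N,N,CB
VAL	O	163	C,CA
VAL	CB	164	CA,CG1,CG2,N,C
VAL	CG1	165	CB,CA,CG2
VAL	CG2	166	CB,CA,CG1
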