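residue	atom	vdw_rmin	vdw_epsilon	charge	solv_dg_free	solv_lambda	solv_volume	donor	acceptor
ALA	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
ALA	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
ALA	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
ALA	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
ALA	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
ARG	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
ARG	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
ARG	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
ARG	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
ARG	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
ARG	CG	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
ARG	CD	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
ARG	NE	1.75	0.170	+0.10	-10.00	6.0	8.0	1	0
ARG	CZ	1.95	0.070	+0.20	+0.00	3.5	10.0	0	0
ARG	NH1	1.75	0.170	+0.35	-10.00	6.0	8.0	1	0
ARG	NH2	1.75	0.170	+0.35	-10.00	6.0	8.0	1	0
ASN	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
ASN	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
ASN	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
ASN	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
ASN	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
ASN	CG	1.95	0.070	+0.00	+0.00	3.5	10.0	0	0
ASN	OD1	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
ASN	ND2	1.75	0.170	-0.25	-5.95	3.5	5.0	1	0
ASP	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
ASP	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
ASP	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
ASP	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
ASP	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
ASP	CG	1.95	0.070	+0.10	+0.00	3.5	10.0	0	0
ASP	OD1	1.70	0.120	-0.55	-10.00	6.0	11.0	0	1
ASP	OD2	1.70	0.120	-0.55	-10.00	6.0	11.0	0	1
CYS	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
CYS	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
CYS	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
CYS	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
CYS	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
CYS	SG	2.00	0.450	-0.10	-3.24	3.5	21.0	0	0
GLN	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
GLN	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
GLN	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
GLN	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
GLN	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
GLN	CG	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
GLN	CD	1.95	0.070	+0.00	+0.00	3.5	10.0	0	0
GLN	OE1	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
GLN	NE2	1.75	0.170	-0.25	-5.95	3.5	5.0	1	0
GLU	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
GLU	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
GLU	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
GLU	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
GLU	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
GLU	CG	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
GLU	CD	1.95	0.070	+0.10	+0.00	3.5	10.0	0	0
GLU	OE1	1.70	0.120	-0.55	-10.00	6.0	11.0	0	1
GLU	OE2	1.70	0.120	-0.55	-10.00	6.0	11.0	0	1
GLY	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
GLY	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
GLY	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
GLY	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
HIS	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
HIS	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
HIS	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
HIS	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
HIS	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
HIS	CG	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
HIS	ND1	1.75	0.170	-0.05	-5.95	3.5	5.0	1	1
HIS	CD2	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
HIS	CE1	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
HIS	NE2	1.75	0.170	-0.05	-5.95	3.5	5.0	1	1
ILE	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
ILE	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
ILE	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
ILE	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
ILE	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
ILE	CG1	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
ILE	CG2	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
ILE	CD1	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
LEU	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
LEU	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
LEU	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
LEU	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
LEU	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
LEU	CG	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
LEU	CD1	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
LEU	CD2	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
LYS	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
LYS	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
LYS	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
LYS	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
LYS	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
LYS	CG	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
LYS	CD	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
LYS	CE	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
LYS	NZ	1.75	0.170	+0.90	-10.00	6.0	8.0	1	0
MET	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
MET	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
MET	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
MET	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
MET	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
MET	CG	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
MET	SD	2.00	0.450	-0.05	-3.24	3.5	21.0	0	0
MET	CE	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
PHE	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
PHE	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
PHE	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
PHE	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
PHE	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
PHE	CG	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
PHE	CD1	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
PHE	CD2	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
PHE	CE1	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
PHE	CE2	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
PHE	CZ	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
PRO	N	1.75	0.170	-0.30	-5.95	3.5	5.0	0	0
PRO	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
PRO	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
PRO	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
PRO	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
PRO	CG	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
PRO	CD	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
SER	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
SER	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
SER	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
SER	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
SER	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
SER	OG	1.70	0.120	-0.35	-6.70	3.5	11.0	1	1
THR	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
THR	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
THR	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
THR	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
THR	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
THR	OG1	1.70	0.120	-0.35	-6.70	3.5	11.0	1	1
THR	CG2	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
TRP	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
TRP	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
TRP	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
TRP	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
TRP	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
TRP	CG	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TRP	CD1	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TRP	CD2	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TRP	NE1	1.75	0.170	-0.15	-5.95	3.5	5.0	1	0
TRP	CE2	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TRP	CE3	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TRP	CZ2	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TRP	CZ3	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TRP	CH2	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TYR	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
TYR	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
TYR	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
TYR	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
TYR	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
TYR	CG	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TYR	CD1	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TYR	CD2	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TYR	CE1	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TYR	CE2	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TYR	CZ	1.95	0.070	+0.00	+0.08	3.5	18.0	0	0
TYR	OH	1.70	0.120	-0.35	-6.70	3.5	11.0	1	1
VAL	N	1.75	0.170	-0.30	-5.95	3.5	5.0	1	0
VAL	CA	1.95	0.070	+0.10	+0.52	3.5	20.0	0	0
VAL	C	1.95	0.070	+0.40	+0.00	3.5	10.0	0	0
VAL	O	1.70	0.120	-0.45	-5.33	3.5	12.0	0	1
VAL	CB	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
VAL	CG1	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
VAL	CG2	1.95	0.070	+0.00	+0.52	3.5	20.0	0	0
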