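residue	atom_name	five_element_type	six_element_type
ALA	C	C;4;3;0;0	C;4;3;0;0;0
ALA	CA	C;4;3;1;0	C;4;3;1;0;0
ALA	CB	C;4;1;3;0	C;4;1;3;0;0
ALA	N	N;3;2;1;0	N;3;2;1;0;0
ALA	O	O;2;1;0;0	O;2;1;0;0;0
ARG	C	C;4;3;0;0	C;4;3;0;0;0
ARG	CA	C;4;3;1;0	C;4;3;1;0;0
ARG	CB	C;4;2;2;0	C;4;2;2;0;0
ARG	CD	C;4;2;2;0	C;4;2;2;0;0
ARG	CG	C;4;2;2;0	C;4;2;2;0;0
ARG	CZ	C;4;3;0;0	C;4;3;0;0;0
ARG	N	N;3;2;1;0	N;3;2;1;0;0
ARG	NE	N;3;2;1;0	N;3;2;1;0;0
ARG	NH1	N;4;1;2;0	N;4;1;2;0;0
ARG	NH2	N;3;1;2;0	N;3;1;2;0;0
ARG	O	O;2;1;0;0	O;2;1;0;0;0
ASN	C	C;4;3;0;0	C;4;3;0;0;0
ASN	CA	C;4;3;1;0	C;4;3;1;0;0
ASN	CB	C;4;2;2;0	C;4;2;2;0;0
ASN	CG	C;4;3;0;0	C;4;3;0;0;0
ASN	N	N;3;2;1;0	N;3;2;1;0;0
ASN	ND2	N;3;1;2;0	N;3;1;2;0;0
ASN	O	O;2;1;0;0	O;2;1;0;0;0
ASN	OD1	O;2;1;0;0	O;2;1;0;0;0
ASP	C	C;4;3;0;0	C;4;3;0;0;0
ASP	CA	C;4;3;1;0	C;4;3;1;0;0
ASP	CB	C;4;2;2;0	C;4;2;2;0;0
ASP	CG	C;4;3;0;0	C;4;3;0;0;0
ASP	N	N;3;2;1;0	N;3;2;1;0;0
ASP	O	O;2;1;0;0	O;2;1;0;0;0
ASP	OD1	O;2;1;0;0	O;2;1;0;0;0
ASP	OD2	O;1;1;0;0	O;1;1;0;0;0
CYS	C	C;4;3;0;0	C;4;3;0;0;0
CYS	CA	C;4;3;1;0	C;4;3;1;0;0
CYS	CB	C;4;2;2;0	C;4;2;2;0;0
CYS	N	N;3;2;1;0	N;3;2;1;0;0
CYS	O	O;2;1;0;0	O;2;1;0;0;0
CYS	SG	S;2;1;1;0	S;2;1;1;0;0
GLN	C	C;4;3;0;0	C;4;3;0;0;0
GLN	CA	C;4;3;1;0	C;4;3;1;0;0
GLN	CB	C;4;2;2;0	C;4;2;2;0;0
GLN	CD	C;4;3;0;0	C;4;3;0;0;0
GLN	CG	C;4;2;2;0	C;4;2;2;0;0
GLN	N	N;3;2;1;0	N;3;2;1;0;0
GLN	NE2	N;3;1;2;0	N;3;1;2;0;0
GLN	O	O;2;1;0;0	O;2;1;0;0;0
GLN	OE1	O;2;1;0;0	O;2;1;0;0;0
GLU	C	C;4;3;0;0	C;4;3;0;0;0
GLU	CA	C;4;3;1;0	C;4;3;1;0;0
GLU	CB	C;4;2;2;0	C;4;2;2;0;0
GLU	CD	C;4;3;0;0	C;4;3;0;0;0
GLU	CG	C;4;2;2;0	C;4;2;2;0;0
GLU	N	N;3;2;1;0	N;3;2;1;0;0
GLU	O	O;2;1;0;0	O;2;1;0;0;0
GLU	OE1	O;2;1;0;0	O;2;1;0;0;0
GLU	OE2	O;1;1;0;0	O;1;1;0;0;0
GLY	C	C;4;3;0;0	C;4;3;0;0;0
GLY	CA	C;4;2;2;0	C;4;2;2;0;0
GLY	N	N;3;2;1;0	N;3;2;1;0;0
GLY	O	O;2;1;0;0	O;2;1;0;0;0
HIS	C	C;4;3;0;0	C;4;3;0;0;0
HIS	CA	C;4;3;1;0	C;4;3;1;0;0
HIS	CB	C;4;2;2;0	C;4;2;2;0;0
HIS	CD2	C;4;2;1;1	C;4;2;1;1;1
HIS	CE1	C;4;2;1;1	C;4;2;1;1;1
HIS	CG	C;4;3;0;1	C;4;3;0;1;1
HIS	N	N;3;2;1;0	N;3;2;1;0;0
HIS	ND1	N;3;2;0;1	N;3;2;0;1;1
HIS	NE2	N;3;2;1;1	N;3;2;1;1;1
HIS	O	O;2;1;0;0	O;2;1;0;0;0
ILE	C	C;4;3;0;0	C;4;3;0;0;0
ILE	CA	C;4;3;1;0	C;4;3;1;0;0
ILE	CB	C;4;3;1;0	C;4;3;1;0;0
ILE	CD1	C;4;1;3;0	C;4;1;3;0;0
ILE	CG1	C;4;2;2;0	C;4;2;2;0;0
ILE	CG2	C;4;1;3;0	C;4;1;3;0;0
ILE	N	N;3;2;1;0	N;3;2;1;0;0
ILE	O	O;2;1;0;0	O;2;1;0;0;0
LEU	C	C;4;3;0;0	C;4;3;0;0;0
LEU	CA	C;4;3;1;0	C;4;3;1;0;0
LEU	CB	C;4;2;2;0	C;4;2;2;0;0
LEU	CD1	C;4;1;3;0	C;4;1;3;0;0
LEU	CD2	C;4;1;3;0	C;4;1;3;0;0
LEU	CG	C;4;3;1;0	C;4;3;1;0;0
LEU	N	N;3;2;1;0	N;3;2;1;0;0
LEU	O	O;2;1;0;0	O;2;1;0;0;0
LYS	C	C;4;3;0;0	C;4;3;0;0;0
LYS	CA	C;4;3;1;0	C;4;3;1;0;0
LYS	CB	C;4;2;2;0	C;4;2;2;0;0
LYS	CD	C;4;2;2;0	C;4;2;2;0;0
LYS	CE	C;4;2;2;0	C;4;2;2;0;0
LYS	CG	C;4;2;2;0	C;4;2;2;0;0
LYS	N	N;3;2;1;0	N;3;2;1;0;0
LYS	NZ	N;4;1;3;0	N;4;1;3;0;0
LYS	O	O;2;1;0;0	O;2;1;0;0;0
MET	C	C;4;3;0;0	C;4;3;0;0;0
MET	CA	C;4;3;1;0	C;4;3;1;0;0
MET	CB	C;4;2;2;0	C;4;2;2;0;0
MET	CE	C;4;1;3;0	C;4;1;3;0;0
MET	CG	C;4;2;2;0	C;4;2;2;0;0
MET	N	N;3;2;1;0	N;3;2;1;0;0
MET	O	O;2;1;0;0	O;2;1;0;0;0
MET	SD	S;2;2;0;0	S;2;2;0;0;0
PHE	C	C;4;3;0;0	C;4;3;0;0;0
PHE	CA	C;4;3;1;0	C;4;3;1;0;0
PHE	CB	C;4;2;2;0	C;4;2;2;0;0
PHE	CD1	C;4;2;1;1	C;4;2;1;1;1
PHE	CD2	C;4;2;1;1	C;4;2;1;1;1
PHE	CE1	C;4;2;1;1	C;4;2;1;1;1
PHE	CE2	C;4;2;1;1	C;4;2;1;1;1
PHE	CG	C;4;3;0;1	C;4;3;0;1;1
PHE	CZ	C;4;2;1;1	C;4;2;1;1;1
PHE	N	N;3;2;1;0	N;3;2;1;0;0
PHE	O	O;2;1;0;0	O;2;1;0;0;0
PRO	C	C;4;3;0;0	C;4;3;0;0;0
PRO	CA	C;4;3;1;1	C;4;3;1;0;1
PRO	CB	C;4;2;2;1	C;4;2;2;0;1
PRO	CD	C;4;2;2;1	C;4;2;2;0;1
PRO	CG	C;4;2;2;1	C;4;2;2;0;1
PRO	N	N;3;3;0;1	N;3;3;0;0;1
PRO	O	O;2;1;0;0	O;2;1;0;0;0
SER	C	C;4;3;0;0	C;4;3;0;0;0
SER	CA	C;4;3;1;0	C;4;3;1;0;0
SER	CB	C;4;2;2;0	C;4;2;2;0;0
SER	N	N;3;2;1;0	N;3;2;1;0;0
SER	O	O;2;1;0;0	O;2;1;0;0;0
SER	OG	O;2;1;1;0	O;2;1;1;0;0
THR	C	C;4;3;0;0	C;4;3;0;0;0
THR	CA	C;4;3;1;0	C;4;3;1;0;0
THR	CB	C;4;3;1;0	C;4;3;1;0;0
THR	CG2	C;4;1;3;0	C;4;1;3;0;0
THR	N	N;3;2;1;0	N;3;2;1;0;0
THR	O	O;2;1;0;0	O;2;1;0;0;0
THR	OG1	O;2;1;1;0	O;2;1;1;0;0
TRP	C	C;4;3;0;0	C;4;3;0;0;0
TRP	CA	C;4;3;1;0	C;4;3;1;0;0
TRP	CB	C;4;2;2;0	C;4;2;2;0;0
TRP	CD1	C;4;2;1;1	C;4;2;1;1;1
TRP	CD2	C;4;3;0;1	C;4;3;0;1;1
TRP	CE2	C;4;3;0;1	C;4;3;0;1;1
TRP	CE3	C;4;2;1;1	C;4;2;1;1;1
TRP	CG	C;4;3;0;1	C;4;3;0;1;1
TRP	CH2	C;4;2;1;1	C;4;2;1;1;1
TRP	CZ2	C;4;2;1;1	C;4;2;1;1;1
TRP	CZ3	C;4;2;1;1	C;4;2;1;1;1
TRP	N	N;3;2;1;0	N;3;2;1;0;0
TRP	NE1	N;3;2;1;1	N;3;2;1;1;1
TRP	O	O;2;1;0;0	O;2;1;0;0;0
TYR	C	C;4;3;0;0	C;4;3;0;0;0
TYR	CA	C;4;3;1;0	C;4;3;1;0;0
TYR	CB	C;4;2;2;0	C;4;2;2;0;0
TYR	CD1	C;4;2;1;1	C;4;2;1;1;1
TYR	CD2	C;4;2;1;1	C;4;2;1;1;1
TYR	CE1	C;4;2;1;1	C;4;2;1;1;1
TYR	CE2	C;4;2;1;1	C;4;2;1;1;1
TYR	CG	C;4;3;0;1	C;4;3;0;1;1
TYR	CZ	C;4;3;0;1	C;4;3;0;1;1
TYR	N	N;3;2;1;0	N;3;2;1;0;0
TYR	O	O;2;1;0;0	O;2;1;0;0;0
TYR	OH	O;2;1;1;0	O;2;1;1;0;0
VAL	C	C;4;3;0;0	C;4;3;0;0;0
VAL	CA	C;4;3;1;0	C;4;3;1;0;0
VAL	CB	C;4;3;1;0	C;4;3;1;0;0
VAL	CG1	C;4;1;3;0	C;4;1;3;0;0
VAL	CG2	C;4;1;3;0	C;4;1;3;0;0
VAL	N	N;3;2;1;0	N;3;2;1;0;0
VAL	O	O;2;1;0;0	O;2;1;0;0;0
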