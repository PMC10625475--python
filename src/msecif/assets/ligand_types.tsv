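six_element_type	five_element_type	witness_smiles	witness_atom_index	comment
B;3;3;0;0;0	B;3;3;0;0	CB(O)O	1	boronic acid B
B;3;3;0;0;1	B;3;3;0;1	CB1OC(C)(C)C(C)(C)O1	1	cyclic boronate B
Br;1;1;0;0;0	Br;1;1;0;0	CBr	1	organobromine
C;4;1;1;0;0	C;4;1;1;0	C#CC	0	terminal alkyne CH
C;4;1;2;0;0	C;4;1;2;0	C=CC	0	terminal alkene CH2
C;4;1;3;0;0	C;4;1;3;0	CC	0	methyl
C;4;2;0;0;0	C;4;2;0;0	CC#CC	1	internal alkyne C
C;4;2;0;0;1	C;4;2;0;1	C1CC#CCCCC1	2	ring alkyne C (cyclooctyne)
C;4;2;1;0;0	C;4;2;1;0	CC=CC	1	acyclic sp2 CH
C;4;2;1;0;1	C;4;2;1;1	C1=CCCCC1	0	non-aromatic ring sp2 CH
C;4;2;1;1;1	C;4;2;1;1	c1ccccc1	0	aromatic CH
C;4;2;2;0;0	C;4;2;2;0	CCC	1	acyclic CH2
C;4;2;2;0;1	C;4;2;2;1	C1CCCCC1	0	ring CH2
C;4;3;0;0;0	C;4;3;0;0	CC(C)=C	1	acyclic sp2 C, trisubstituted
C;4;3;0;0;1	C;4;3;0;1	O=C1CCCCC1	1	ring carbonyl carbon
C;4;3;0;1;1	C;4;3;0;1	Cc1ccccc1	1	substituted aromatic C
C;4;3;1;0;0	C;4;3;1;0	CC(C)C	1	acyclic CH
C;4;3;1;0;1	C;4;3;1;1	CC1CCCCC1	1	ring CH
C;4;4;0;0;0	C;4;4;0;0	CC(C)(C)C	1	quaternary C
C;4;4;0;0;1	C;4;4;0;1	CC1(C)CCCCC1	1	ring quaternary C
Cl;1;1;0;0;0	Cl;1;1;0;0	CCl	1	organochlorine
F;1;1;0;0;0	F;1;1;0;0	CF	1	organofluorine
I;1;1;0;0;0	I;1;1;0;0	CI	1	organoiodine
N;2;1;0;0;0	N;2;1;0;0	CN=[N+]=[N-]	3	azide terminal N
N;2;1;1;0;0	N;2;1;1;0	CS(=O)(=O)[NH-]	4	deprotonated primary sulfonamide
N;2;2;0;0;0	N;2;2;0;0	CS(=O)(=O)[N-]C	4	deprotonated secondary sulfonamide
N;3;1;0;0;0	N;3;1;0;0	CC#N	2	nitrile N
N;3;1;1;0;0	N;3;1;1;0	CC(=N)N	2	terminal imine NH
N;3;1;2;0;0	N;3;1;2;0	CN	1	primary amine
N;3;2;0;0;0	N;3;2;0;0	CC=NC	2	acyclic imine N
N;3;2;0;0;1	N;3;2;0;1	C1CCC=N1	4	cyclic imine N
N;3;2;0;1;1	N;3;2;0;1	c1ccncc1	3	pyridine-type aromatic N
N;3;2;1;0;0	N;3;2;1;0	CNC	1	secondary amine / amide NH
N;3;2;1;0;1	N;3;2;1;1	C1CCNCC1	3	saturated ring NH
N;3;2;1;1;1	N;3;2;1;1	c1cc[nH]c1	3	pyrrole-type aromatic NH
N;3;3;0;0;0	N;3;3;0;0	CN(C)C	1	tertiary amine
N;3;3;0;0;1	N;3;3;0;1	CN1CCCCC1	1	N-substituted saturated ring N
N;3;3;0;1;1	N;3;3;0;1	Cn1cccc1	1	N-substituted aromatic N
N;4;1;2;0;0	N;4;1;2;0	CC(N)=[NH2+]	3	amidinium =NH2+
N;4;1;3;0;0	N;4;1;3;0	C[NH3+]	1	primary ammonium
N;4;2;0;0;0	N;4;2;0;0	CN=[N+]=[N-]	2	azide central N
N;4;2;1;0;0	N;4;2;1;0	CC=[NH+]C	2	protonated acyclic imine
N;4;2;1;0;1	N;4;2;1;1	C1CCC=[NH+]1	4	protonated cyclic imine
N;4;2;1;1;1	N;4;2;1;1	c1cc[nH+]cc1	3	pyridinium NH+
N;4;2;2;0;0	N;4;2;2;0	C[NH2+]C	1	secondary ammonium
N;4;2;2;0;1	N;4;2;2;1	C1CC[NH2+]CC1	3	ring secondary ammonium
N;4;3;0;0;0	N;4;3;0;0	C[N+](=O)[O-]	1	nitro N (charge-separated)
N;4;3;0;0;1	N;4;3;0;1	C[N+]1=CCCC1	1	ring iminium N
N;4;3;0;1;1	N;4;3;0;1	C[n+]1ccccc1	1	N-substituted pyridinium
N;4;3;1;0;0	N;4;3;1;0	C[NH+](C)C	1	tertiary ammonium
N;4;3;1;0;1	N;4;3;1;1	C[NH+]1CCCCC1	1	ring tertiary ammonium
N;4;4;0;0;0	N;4;4;0;0	C[N+](C)(C)C	1	quaternary ammonium
N;4;4;0;0;1	N;4;4;0;1	C[N+]1(C)CCCCC1	1	ring quaternary ammonium
O;1;1;0;0;0	O;1;1;0;0	CC(=O)[O-]	3	oxide / carboxylate O-
O;2;1;0;0;0	O;2;1;0;0	CC(=O)C	2	carbonyl O
O;2;1;1;0;0	O;2;1;1;0	CO	1	hydroxyl
O;2;2;0;0;0	O;2;2;0;0	COC	1	acyclic ether/ester O
O;2;2;0;0;1	O;2;2;0;1	C1CCOC1	3	saturated ring O
O;2;2;0;1;1	O;2;2;0;1	c1ccoc1	3	furan-type aromatic O
P;3;3;0;0;0	P;3;3;0;0	CP(C)C	1	phosphine
P;3;3;0;0;1	P;3;3;0;1	CP1CCCC1	1	ring phosphine
P;4;4;0;0;0	P;4;4;0;0	C[P+](C)(C)C	1	phosphonium
P;5;3;1;0;0	P;5;3;1;0	COP(=O)OC	2	H-phosphonate P
P;5;4;0;0;0	P;5;4;0;0	COP(=O)(OC)OC	2	phosphate/phosphonate P
P;5;4;0;0;1	P;5;4;0;1	O=P1(O)OCCO1	1	cyclic phosphate P
S;1;1;0;0;0	S;1;1;0;0	C[S-]	1	thiolate
S;2;1;0;0;0	S;2;1;0;0	NC(=S)N	2	thiocarbonyl S
S;2;1;1;0;0	S;2;1;1;0	CS	1	thiol
S;2;2;0;0;0	S;2;2;0;0	CSC	1	acyclic thioether
S;2;2;0;0;1	S;2;2;0;1	C1CCSC1	3	saturated ring S
S;2;2;0;1;1	S;2;2;0;1	c1ccsc1	3	thiophene-type aromatic S
S;3;3;0;0;0	S;3;3;0;0	C[S+](C)C	1	sulfonium
S;3;3;0;0;1	S;3;3;0;1	C[S+]1CCCC1	1	ring sulfonium
S;4;3;0;0;0	S;4;3;0;0	CS(=O)C	1	sulfoxide
S;4;3;0;0;1	S;4;3;0;1	O=S1CCCC1	1	cyclic sulfoxide
S;6;4;0;0;0	S;6;4;0;0	CS(C)(=O)=O	1	sulfone / sulfonamide S
S;6;4;0;0;1	S;6;4;0;1	O=S1(=O)CCCC1	1	cyclic sulfone
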