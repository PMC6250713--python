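name	family	pattern	anchors	requires_amide	note
MIP_W6W	MIP	W x{6} W	c_terminal	true	myoinhibitory peptide classic core W(6x)W-amide
MIP_W7W	MIP	W x{7} W	c_terminal	true	hemipteran variant core W(7x)W-amide
kinin_FXXWG	kinin	F x{2} W G	c_terminal	true	conserved insect kinin core FXXWG-amide
kinin_FSXWA	kinin	F S x W A	c_terminal	true	heteropteran variant core FSXWA-amide
FMRFamide	FMRFamide	F M R F	c_terminal	true	classic FMRF-amide C-terminus
FIRFamide	FMRFamide	F I R F	c_terminal	true	infrequent heteropteran FIRF-amide variant
myosuppressin_FLRF	myosuppressin	F L R F	c_terminal	true	myosuppressin core C-terminus FLRF-amide
sulfakinin_GHMRF	sulfakinin	G H M R F	c_terminal	true	frequent sulfakinin C-terminus GHMRF-amide
sulfakinin_GYMRF	sulfakinin	G Y M R F	c_terminal	true	unusual heteropteran GYMRF-amide paracopy
FGL_AST	FGL-AST	F G L	c_terminal	true	allatostatin A core FGL-amide
LGL_AST	FGL-AST	L G L	c_terminal	true	unusual first-copy LGL-amide variant
ETH_PRX	ETH	P R [LIVM]	c_terminal	true	ecdysis triggering hormone core PRXamide
RYamide_RY	RYamide	R Y	c_terminal	true	RYamide C-terminus
RYamide_FY3XRY	RYamide	F Y x{3} R Y	c_terminal	true	provisional encoding of the ambiguous FY3(X)RY-amide prose motif
AKH_core	AKH	Q x{6} W x{0,2}	n_terminal,c_terminal	true	adipokinetic hormone: pyroGlu start, W at position 8, length 8-10
CNMamide_CNM	CNMamide	C N M	c_terminal	true	CNMamide core C-terminus
sNPF_RLRF	sNPF	R [LS] R F	c_terminal	true	short neuropeptide F core C-terminus
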