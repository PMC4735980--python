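# Bundled restriction enzyme panel (REBASE-style caret notation: the caret
# marks the top-strand cut within the recognition site).
# Columns: name, site with caret.
AluI	AG^CT
DdeI	C^TNAG
EcoRI	G^AATTC
HaeIII	GG^CC
HhaI	GCG^C
HindIII	A^AGCTT
HinfI	G^ANTC
MseI	T^TAA
MspI	C^CGG
RsaI	GT^AC
Sau3AI	^GATC
TaqI	T^CGA
TfiI	G^AWTC
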