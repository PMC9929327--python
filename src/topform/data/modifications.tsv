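accession	name	delta	composition	sites	category
0	SDS	266.155180	C12H26O4S	*	adduct
1	Acetyl	42.010565	C2H2O	K,N-term	PTM
21	Phospho	79.966331	HO3P	S,T,Y	PTM
23	Dehydrated	-18.010565	H(-2)O(-1)	S,T,Y,D	PTM
34	Methyl	14.015650	CH2	K,R,C,H,N,Q,N-term	PTM
35	Oxidation	15.994915	O	M,W,H,C,F,Y	PTM
36	Dimethyl	28.031300	C2H4	K,R,N-term	PTM
122	Formyl	27.994915	CO	K,S,T,N-term	PTM
342	Amino	15.010899	HN	Y	PTM
401	Didehydro	-2.015650	H(-2)	C,S,T,Y,K	PTM
419	Glycerophospho	154.003110	C3H7O5P	S	PTM
421	Sulfide	31.972071	S	C,D	PTM
425	Dioxidation	31.989829	O2	M,W,C,F,P,K,R	PTM
449	Decanoyl	154.135765	C10H18O	S,T,C	PTM
528	Methyl+Deamidated	14.999666	CHN(-1)O	N,Q	PTM
721	ONE	154.099380	C9H14O2	C,H,K	PTM
765	Met-loss	-131.040485	C(-5)H(-9)N(-1)O(-1)S(-1)	M,N-term	artefact
1145	Met->Glu	-1.997892	H(-2)O2S(-1)	M	PTM
1217	Val->Pro	-2.015650	H(-2)	V	PTM
1289	Butyryl	70.041865	C4H6O	K	PTM
2020	Disulfide	-2.015650	H(-2)	C	PTM
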