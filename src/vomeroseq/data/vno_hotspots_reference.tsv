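chrom	start	end	n_expressed	n_de	families
6	48448229	48754210	25	11	GIMAP
6	56172928	57664632	39	14	Vmn1r (Clade C)
6	89316314	90600203	46	19	Vmn1r (Clades A, B)
6	123195632	124082601	27	11	Clec, Vmn2r (Clade B)
6	128648576	129740484	62	28	Clec, Klr
6	136506167	138079916	30	12	NA
7	7171330	9389264	67	32	Vmn2r (Clade A4)
7	23272801	24143241	41	18	Vmn1r (Clade D)
7	104140623	104601779	32	13	Olfr, Trim
16	44347121	47758671	40	17	Cd200, Cd200r
17	17830352	20405756	44	19	Fpr, Vmn2r (Clade A8)
17	34031812	36198513	122	47	Btnl, MHC (Clades IIa, IIb, Ia, Ib)
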