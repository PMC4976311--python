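gene	type	start	end	frame_anchor	strand	complex
CR_5p	control_region	1	576		+	none
tRNA-Phe	tRNA	577	647		+	none
12S-rRNA	rRNA	648	1601		+	none
tRNA-Val	tRNA	1602	1670		+	none
16S-rRNA	rRNA	1671	3229		+	none
tRNA-Leu(UUR)	tRNA	3230	3304		+	none
ND1	protein	3307	4262	3307	+	I
tRNA-Ile	tRNA	4263	4331		+	none
tRNA-Gln	tRNA	4329	4400		-	none
tRNA-Met	tRNA	4402	4469		+	none
ND2	protein	4470	5511	4470	+	I
tRNA-Trp	tRNA	5512	5579		+	none
tRNA-Ala	tRNA	5587	5655		-	none
tRNA-Asn	tRNA	5657	5729		-	none
tRNA-Cys	tRNA	5761	5826		-	none
tRNA-Tyr	tRNA	5826	5891		-	none
COX1	protein	5904	7445	5904	+	IV
tRNA-Ser(UCN)	tRNA	7446	7514		-	none
tRNA-Asp	tRNA	7518	7585		+	none
COX2	protein	7586	8269	7586	+	IV
tRNA-Lys	tRNA	8295	8364		+	none
ATP8	protein	8366	8572	8366	+	V
ATP6	protein	8527	9207	8527	+	V
COX3	protein	9207	9990	9207	+	IV
tRNA-Gly	tRNA	9991	10058		+	none
ND3	protein	10059	10404	10059	+	I
tRNA-Arg	tRNA	10405	10469		+	none
ND4L	protein	10470	10766	10470	+	I
ND4	protein	10760	12137	10760	+	I
tRNA-His	tRNA	12138	12206		+	none
tRNA-Ser(AGY)	tRNA	12207	12265		+	none
tRNA-Leu(CUN)	tRNA	12266	12336		+	none
ND5	protein	12337	14148	12337	+	I
ND6	protein	14149	14673	14673	-	I
tRNA-Glu	tRNA	14674	14742		-	none
CYB	protein	14747	15887	14747	+	III
tRNA-Thr	tRNA	15888	15953		+	none
tRNA-Pro	tRNA	15956	16023		-	none
CR_3p	control_region	16024	16569		+	none
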