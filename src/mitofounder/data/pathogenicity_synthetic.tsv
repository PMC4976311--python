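variant	gene	disease	mutpred	ci
T3394C	ND1	LHON/NIDDM/CPT deficiency	0.783	0.942
A636G	tRNA-Phe	DEAF		0.673
T9101C	ATP6	LHON	0.568	0.346
G13708A	ND5	LHON/Increased MS risk	0.409	0.365
C1192A	12S-rRNA	DEAF-associated		0.827
A3397G	ND1	PD, AD / possibly LVNC-cardiomyopathy	0.723	1.000
G7598A	COX2	Possible LHON helper	0.342	0.865
T2352C	16S-rRNA	Possibly LVNC-associated		0.058
T4363C	tRNA-Gln	Possibly DEAF + RP / hypertension		0.750
G7697A	COX2	Possible HCM susceptibility	0.646	0.981
T10454C	tRNA-Arg	DEAF helper mutation		0.692
T1005C	12S-rRNA	DEAF		0.250
T4216C	ND1	LHON/Insulin Resistance	0.611	0.712
A15924G	tRNA-Thr	LIMM		0.865
A12634G	ND5	Thyroid Cancer Cell Line	0.381	1.000
T3310C	ND1	synthetic synonymous filler	0.100	0.050
A3312G	ND1	synthetic synonymous filler	0.100	0.050
C3315A	ND1	synthetic synonymous filler	0.100	0.050
G16100A	CR_3p	synthetic control-region filler		0.010
A200G	CR_5p	synthetic control-region filler		0.010
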