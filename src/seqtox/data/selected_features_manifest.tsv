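group	name
protr_ctd	prop2.G2.residue25
protr_ctd	prop1.G3.residue0
protr_ctd	prop7.G3.residue0
protr_ctd	prop7.G1.residue25
protr_ctd	prop5.G2.residue0
protr_ctd	prop1.G3.residue25
protr_ctd	prop5.G2.residue25
protr_ctd	prop6.G1.residue75
protr_ctd	prop5.G3.residue0
protr_ctd	prop6.G1.residue50
protr_ctd	prop5.G1.residue0
protr_ctd	prop2.G2.residue50
protr_ctd	prop2.G3.residue0
protr_ctd	prop1.G2.residue0
protr_ctd	prop6.G1.residue0
protr_ctd	prop2.G2.residue75
protr_ctd	prop2.G1.residue25
protr_ctd	secondarystruct.Group2
protr_ctd	prop6.G3.residue25
protr_ctd	prop7.G1.residue50
protr_ctd	prop7.G3.residue100
protr_ctd	prop7.G1.residue0
protr_ctd	prop5.G3.residue100
protr_ctd	prop1.G1.residue25
protr_ctd	prop6.G3.residue0
protr_ctd	prop5.G3.residue75
protr_ctd	prop1.G3.residue50
protr_ctd	secondarystruct.Group1
protr_ctd	prop2.G2.residue0
protr_ctriad	VS362
protr_ctriad	VS261
protr_ctriad	VS131
protr_ctriad	VS314
protr_ctriad	VS552
protr_ctriad	VS236
protr_ctriad	VS215
protr_ctriad	VS136
protr_ctriad	VS722
protr_ctriad	VS652
protr_ctriad	VS216
protr_ctriad	VS327
protr_dpc	SL
protr_dpc	CS
protr_dpc	QL
protr_dpc	CC
protr_dpc	VE
protr_dpc	HC
protr_dpc	CY
protr_dpc	VC
protr_dpc	RV
protr_dpc	GY
protr_dpc	EI
protr_dpc	GA
protr_dpc	LA
protr_dpc	ID
protr_dpc	VR
protr_dpc	DI
protr_dpc	AL
protr_dpc	QA
protr_dpc	CF
protr_dpc	SC
protr_dpc	CE
protr_mb	CHAM820102.lag3
protr_mb	CHAM820102.lag30
protr_qso	Schneider.Xd.28
protr_qso	Schneider.Xd.27
protr_apaac	Pc1.N
protr_apaac	Pc1.A
protr_apaac	Pc1.C
protr_geary	CIDH920105.lag1
protr_aac	C
protr_aac	Q
AAindex	FASG760104
AAindex	QIAN880117
AAindex	GEOR030101
AAindex	RISJ880101
AAindex	BEGF750102
AAindex	BURA740102
AAindex	BEGF750101
AAindex	SUYM030101
PSSM	PSSM_W
PSSM	PSSM_C
PSSM	PSSM_Q
PSSM	PSSM_S
PSSM	PSSM_N
PSSM	PSSM_G
PSSM	PSSM_F
PSSM	PSSM_A
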