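APP	pp	PSEN1
APP	pp	MAPT
APP	pp	NCSTN
APP	pp	APOE
APP	pp	ABCA1
APP	pp	CLU
APP	pp	A2M
APP	pp	CTSC
APP	pp	CTSD
APP	pp	SERPINA3
APP	pp	CASP4
APP	pp	GNB2
APP	pp	GNB1
APP	pp	PRKCA
APP	pp	APBA1
APP	pp	NTRK2
APP	pp	HSD17B10
APOE	pp	CLU
APOE	pp	ABCA1
APOE	pp	A2M
APOE	pp	MAPT
APOE	pp	PSEN1
APOE	pp	SERPINA3
APOE	pp	CTSD
MAPT	pp	PSEN1
MAPT	pp	NCSTN
MAPT	pp	CLU
MAPT	pp	NTRK2
MAPT	pp	PRKCZ
MAPT	pp	PRKCG
CLU	pp	A2M
CLU	pp	CTSD
CLU	pp	CASP4
CLU	pp	SERPINA3
PSEN1	pp	NCSTN
PSEN1	pp	APBA1
GNB2	pp	GNB1
GNB2	pp	PRKCA
GNB2	pp	PRKCZ
GNB2	pp	PRKCG
NTRK1	pp	NTRK2
NTRK1	pp	PRKCA
NTRK1	pp	MPO
HSD17B10	pp	UQCRC2
UQCRC2	pp	GNB1
MPO	pp	SERPINA3
MPO	pp	A2M
CTSC	pp	CTSD
APBA1	pp	NTRK2
PRKCA	pp	PRKCZ
PRKCZ	pp	PRKCG
CASP4	pp	A2M
CTSD	pp	SERPINA3
ABCA1	pp	CLU
GNB1	pp	PRKCG
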