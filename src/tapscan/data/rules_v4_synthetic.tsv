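# Synthetic reconstruction of the TAPscan v4 classification rules.
# One rule per line: family_id <TAB> class <TAB> field...
# Fields: required clause (DOM or DOM|DOM), forbidden domain (!DOM),
# best-of pair (DOM>DOM), parent=FAMILY, output=LABEL.
HD_TALE	TF	Homeobox_KN
HD_TALE_KNOX	TF	Homeobox_KN	KNOX1|KNOX2	KNOX1>KNOX2	parent=HD_TALE
HD_TALE_BEL	TF	Homeobox_KN	POX	parent=HD_TALE
HDZ	TF	Homeobox	HALZ
C1HDZ	TF	C1HDZ	parent=HDZ
C2HDZ	TF	C2HDZ	parent=HDZ
C3HDZ	TF	Homeobox	HALZ	START	parent=HDZ
C4HDZ	TF	Homeobox	HALZ	MEKHLA	parent=HDZ
ZPR	TF	ZPR	!Homeobox
HD-LD	TF	HD-LD
HD-NDX	TF	Homeobox	NDX
HD-SAWADEE	TF	Homeobox	SAWADEE
HD_PLINC	TF	Homeobox	ZF-HD_dimer
HD_WOX	TF	Homeobox_WOX
HD_PINTOX	TF	Homeobox	PINTOX
AP2	TF	AP2	!B3
CRF	TF	AP2	CRF	parent=AP2
ARF	TF	B3	Auxin_resp
ABI3/VP1	TF	B3	!AP2	!Auxin_resp
RAV	TF	AP2	B3
bZIP1	TF	bZIP_1	output=bZIP
bZIP2	TF	bZIP_2	output=bZIP
bZIPCDD	TF	bZIP_CDD	output=bZIP
bZIPAUREO	TF	bZIP_AUREO	output=bZIP
GARP_ARR-B_1	TF	Response_reg	G2-like	output=GARP_ARR-B
GARP_ARR-B_2	TF	ARR-B_motif	output=GARP_ARR-B
GARP_G2-like	TF	G2-like	!Response_reg
Pseudo_ARR-B	TF	Response_reg	CCT
C2C2_CO-like	TF	CCT	zf-B_box	!Response_reg
C2C2_Dof	TF	zf-Dof
C2C2_GATA	TF	GATA
C2C2_LSD	TF	zf-LSD1
C2C2_YABBY	TF	YABBY
C2H2	TF	zf-C2H2
C2H2-IDD	TF	zf-C2H2	IDD	parent=C2H2
C3H	TF	zf-CCCH|zf-CCCH_2
NF-X1	TF	zf-NF-X1
MYB	TF	Myb_2R|Myb_3R|Myb_4R
MYB-2R	TF	Myb_2R	parent=MYB
MYB-3R	TF	Myb_3R	parent=MYB
MYB-4R	TF	Myb_4R	parent=MYB
MYB-related	TF	Myb_DNA-binding	!Myb_2R	!Myb_3R	!Myb_4R	!Response_reg	!G2-like
SWI/SNF_SWI3	TR	Myb_DNA-binding	SWIRM	parent=MYB-related
LBD	TF	LOB
LOB1	TF	LOB	!LOB2_motif	parent=LBD
LOB2	TF	LOB2_motif	parent=LBD
bHLH	TF	HLH
bHLH_MYC	TF	HLH	bHLH-MYC_N	parent=bHLH
NF-YA	TF	CBFB_NFYA
NF-YB	TF	CBFD_NFYB
NF-YC	TF	NF-YC
RKD	TF	RWP-RK	!PB1_NLP
NLP	TF	RWP-RK	PB1_NLP
ET	TF	HRT|GIY_YIG
ALOG	TF	ALOG
Alfin-like	TF	Alfin
BBR/BPC	TF	GAGA_bind
BES1	TF	BES1_N
CAMTA	TF	CG-1
CPP	TF	CXC
CSD	TF	CSD	zf-CCHC
CudA	TF	CudA
E2F/DP	TF	E2F_TDP
EIL	TF	EIN3
FHA	TF	FHA
GeBP	TF	DUF573
GRAS	TF	GRAS
GRF	TF	WRC	QLQ
HSF	TF	HSF_DNA-bind
LFY	TF	FLO_LFY
LIM	TF	LIM
MADS	TF	SRF-TF
NAC	TF	NAM
PLATZ	TF	PLATZ
RF-X	TF	RFX_DNA_binding
S1Fa-like	TF	S1FA
SAP	TF	SAP_motif
SBP	TF	SBP
Sigma70-like	TF	Sigma70_r2|Sigma70_r3	Sigma70_r2>Sigma70_r3
SRS	TF	DUF702
STAT	TF	STAT_bind	SH2
TCP	TF	TCP
Tify	TF	tify	CCT_2
Trihelix	TF	trihelix
TUB	TF	TUB
VOZ	TF	VOZ
Whirly	TF	Whirly
WRKY	TF	WRKY
MADS_MIKC	TF	SRF-TF	K-box	parent=MADS
HD_other	TF	Homeobox	!HALZ	!Homeobox_KN	!NDX	!SAWADEE	!ZF-HD_dimer	!PINTOX	!PHD	!DDT	!START	!MEKHLA
HD_PHD	TF	Homeobox	PHD
HD_DDT	TF	Homeobox	DDT
FAR1	TF	FAR1
AHL	TF	AT_hook	DUF296
zn-clus	TF	Zn_clus|Fungal_trans
Forkhead	TF	Forkhead
HAT	TR	Acetyltransf_1|MOZ_SAS|KAT11|Bromo_TAF250|DUF3591
GNAT	TR	Acetyltransf_1	parent=HAT
MYST	TR	MOZ_SAS	parent=HAT
CBP	TR	KAT11	zf-TAZ	parent=HAT
TAF_II_250	TR	Bromo_TAF250|DUF3591	parent=HAT
ADA2	TR	ADA2
LDL/FLD	TR	SWIRM	Amino_oxidase
ARID	TR	ARID
Argonaute	TR	Piwi	PAZ
Aux/IAA	TR	AUX_IAA	!B3
BSD	TR	BSD
Bromodomain	TR	Bromodomain	!Bromo_TAF250
DCL	TR	Dicer_dimer	Helicase_C	Ribonuclease_3
DDT	TR	DDT	!Homeobox
GIF	TR	SSXT
HD2	TR	HD2
HDA1	TR	Hist_deacetyl
HMG	TR	HMG_box	!ARID
Jumonji	TR	JmjC|JmjN
LUG	TR	LUFS	WD40
MBF1	TR	MBF1
MED6	TR	Med6
MED7	TR	Med7
mTERF	TR	mTERF
NOT2_3_5	TR	NOT2_3_5
O-FucT	TR	O-FucT
PHD	TR	PHD	!Alfin	!DDT	!JmjC	!Homeobox
PWWP	TR	PWWP
Rcd1-like	TR	Rcd1
SAP30	TR	SAP30
SET	TR	SET
Sin3	TR	PAH
Sir2	TR	SIR2
SNF2	TR	SNF2_N	Helicase_C
SOH1	TR	Med31
SWI/SNF_BAF60b	TR	SWIB
TRAF	TR	MATH|BTB
zf-MIZ	TR	zf-MIZ
PcG_FIE	TR	WD40_FIE
PcG_VEFS	TR	VEFS-Box
NZZ	PT	NOZZLE
ULT	PT	ULT
VARL	PT	VARL
Coactivator_p15	PT	PC4
IWS1	PT	Med26
DBP	PT	DNC	PP2Cc
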