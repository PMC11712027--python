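# Synthetic reconstruction of the TAPscan v4 coverage values and profile metadata.
# profile <TAB> coverage ('-' = default 0.75) <TAB> GA threshold (bits) <TAB> match states <TAB> origin
ADA2	-	16.4	255	custom_hmm
ALOG	-	31.9	80	pfam
AP2	-	27.1	280	pfam
ARID	-	18.7	260	pfam
ARR-B_motif	-	25.2	155	custom_domain
AT_hook	-	31.9	165	pfam
AUX_IAA	-	30.2	305	pfam
Acetyltransf_1	-	21.9	80	pfam
Alfin	-	25.9	60	pfam
Amino_oxidase	-	29.4	310	pfam
Auxin_resp	0.8	21.3	95	pfam
B3	-	21.7	95	pfam
BES1_N	-	21.9	160	pfam
BSD	-	25.6	245	pfam
BTB	0.5	21.3	315	pfam
Bromo_TAF250	-	16.7	270	pfam
Bromodomain	-	24.0	250	pfam
C1HDZ	-	20.9	60	custom_domain
C2HDZ	-	19.3	315	custom_domain
CBFB_NFYA	-	31.8	155	pfam
CBFD_NFYB	-	28.7	230	pfam
CCT	-	23.6	175	pfam
CCT_2	-	14.4	90	pfam
CG-1	-	23.6	185	pfam
CRF	-	15.7	115	custom_domain
CSD	-	29.6	220	pfam
CXC	-	24.8	70	pfam
CudA	0.5	22.4	305	custom_domain
DDT	-	26.2	290	pfam
DNC	-	23.5	85	pfam
DUF296	-	26.3	85	pfam
DUF3591	0.8	16.4	205	custom_hmm
DUF573	-	31.2	260	pfam
DUF702	0.5	16.3	275	pfam
Dicer_dimer	-	16.9	310	pfam
E2F_TDP	-	19.9	135	pfam
EIN3	-	17.1	100	pfam
FAR1	-	16.4	255	custom_hmm
FHA	-	21.9	205	pfam
FLO_LFY	0.8	31.9	50	pfam
Forkhead	0.5	17.4	65	pfam
Fungal_trans	-	19.4	210	pfam
G2-like	0.8	25.1	95	pfam
GAGA_bind	-	19.6	105	pfam
GATA	-	17.4	215	pfam
GIY_YIG	-	14.6	115	pfam
GRAS	-	30.6	100	pfam
HALZ	-	14.9	230	pfam
HD-LD	-	21.9	145	custom_domain
HD2	0.5	20.5	240	custom_domain
HLH	-	20.6	125	pfam
HMG_box	-	26.4	175	pfam
HRT	-	19.5	80	custom_hmm
HSF_DNA-bind	-	29.3	100	pfam
Helicase_C	-	27.2	70	pfam
Hist_deacetyl	-	30.5	185	pfam
Homeobox	-	19.1	165	pfam
Homeobox_KN	-	16.4	40	pfam
Homeobox_WOX	-	17.6	120	custom_domain
IDD	-	22.7	165	custom_domain
JmjC	-	28.9	240	pfam
JmjN	-	22.3	290	pfam
K-box	-	19.7	125	pfam
KAT11	-	16.7	70	custom_hmm
KNOX1	-	26.0	75	pfam
KNOX2	-	30.2	160	pfam
LIM	-	14.2	265	pfam
LOB	-	27.4	185	pfam
LOB2_motif	-	15.8	175	custom_domain
LUFS	-	27.2	195	pfam
MATH	-	15.9	180	pfam
MBF1	0.8	27.4	185	pfam
MEKHLA	-	16.0	65	pfam
MOZ_SAS	0.5	23.5	70	pfam
Med26	-	21.4	295	pfam
Med31	0.5	17.5	275	pfam
Med6	-	29.1	215	pfam
Med7	-	27.9	140	pfam
Myb_2R	-	26.1	80	custom_domain
Myb_3R	-	25.6	315	custom_domain
Myb_4R	-	31.3	270	custom_domain
Myb_DNA-binding	-	16.5	275	pfam
NAM	0.5	29.1	240	pfam
NDX	0.5	18.3	165	custom_domain
NF-YC	-	20.2	70	pfam
NOT2_3_5	-	26.1	130	pfam
NOZZLE	-	30.3	205	pfam
O-FucT	-	24.9	85	pfam
PAH	-	15.6	95	pfam
PAZ	-	15.8	225	pfam
PB1_NLP	-	19.2	230	custom_hmm
PC4	0.5	29.3	165	pfam
PHD	-	26.5	60	pfam
PINTOX	0.5	21.4	220	custom_domain
PLATZ	-	22.8	315	pfam
POX	0.5	25.3	245	pfam
PP2Cc	0.8	22.0	140	pfam
PWWP	-	25.1	165	pfam
Piwi	-	15.9	45	pfam
QLQ	-	18.0	105	pfam
RFX_DNA_binding	0.8	17.0	90	pfam
RWP-RK	-	17.1	155	pfam
Rcd1	-	19.2	290	pfam
Response_reg	-	16.9	160	pfam
Ribonuclease_3	-	23.3	125	pfam
S1FA	-	19.2	165	pfam
SAP30	-	30.4	310	pfam
SAP_motif	-	23.7	200	pfam
SAWADEE	-	15.0	110	custom_domain
SBP	-	25.4	270	pfam
SET	-	21.2	165	pfam
SH2	-	30.8	65	pfam
SIR2	-	23.4	225	pfam
SNF2_N	-	29.9	40	pfam
SRF-TF	-	15.7	185	pfam
SSXT	-	21.3	240	pfam
START	-	16.1	100	pfam
STAT_bind	-	14.6	55	pfam
SWIB	-	17.4	80	pfam
SWIRM	0.5	20.7	65	pfam
Sigma70_r2	-	19.7	190	pfam
Sigma70_r3	0.8	24.5	250	pfam
TCP	-	24.1	225	pfam
TUB	0.5	21.0	220	pfam
ULT	-	17.2	95	custom_domain
VARL	-	16.4	130	custom_domain
VEFS-Box	-	17.8	165	pfam
VOZ	-	24.8	145	custom_domain
WD40	0.5	17.2	135	pfam
WD40_FIE	-	16.0	280	custom_hmm
WRC	-	19.7	70	pfam
WRKY	0.8	28.6	225	pfam
Whirly	-	21.6	235	pfam
YABBY	-	25.9	305	pfam
ZF-HD_dimer	-	28.1	120	pfam
ZPR	-	31.4	45	custom_domain
Zn_clus	-	16.2	40	pfam
bHLH-MYC_N	0.8	17.4	280	pfam
bZIP_1	0.5	18.0	65	custom_domain
bZIP_2	-	21.0	295	custom_domain
bZIP_AUREO	-	18.8	45	custom_hmm
bZIP_CDD	-	21.0	190	custom_hmm
mTERF	0.5	29.5	165	pfam
tify	-	16.4	100	pfam
trihelix	-	22.6	170	custom_domain
zf-B_box	-	23.3	250	pfam
zf-C2H2	0.5	19.6	200	pfam
zf-CCCH	0.8	17.2	180	pfam
zf-CCCH_2	-	30.7	255	pfam
zf-CCHC	-	29.8	75	pfam
zf-Dof	-	23.8	160	pfam
zf-LSD1	-	22.2	125	pfam
zf-MIZ	-	19.7	185	pfam
zf-NF-X1	-	27.5	170	pfam
zf-TAZ	-	28.3	190	pfam
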