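# Synthetic species table for the packaged signaling network (initials in uM).
species_id	name	initial_uM	boundary	tags
TAM	tamoxifen (clamped input)	250	1	input:tamoxifen
GPR30	GPR30/GPER receptor	0.3	0	
TAM_GPR30	TAM_GPR30	0	0	
Gabg	Gabg	1	0	
Ga_GTP	Ga_GTP	0	0	
Gbg	Gbg	0	0	
Ga_GDP	Ga_GDP	0	0	
AC	AC	0.5	0	
Ga_AC	Ga_AC	0	0	
cAMP	cAMP	0	0	
AMP	AMP	0	0	
PKA	PKA	0.5	0	
cAMP_PKA	cAMP_PKA	0	0	
Raf1_act	Raf1_act	0	0	observable:Raf1_active
Raf1	Raf1	0.5	0	
PLC	PLC	0.5	0	
Gbg_PLC	Gbg_PLC	0	0	
PIP2	PIP2	5	0	
IP3	IP3	0	0	
DAG	DAG	0	0	
Ins	Ins	0	0	
MAG	MAG	0	0	
PKC	PKC	1	0	
PKC_IP3	PKC_IP3	0	0	
PKC_DAG	PKC_DAG	0	0	
PI	PI	10	0	
Src	Src	0.5	0	
Gbg_Src	Gbg_Src	0	0	
Src_act	Src_act	0	0	
MMP	MMP	0.5	0	
MMP_act	MMP_act	0	0	
proHBEGF	proHBEGF	1	0	
EGF	EGF	0	0	
proHBEGF_pool	proHBEGF_pool	1	1	
Shc	Shc	1	0	
Shc_p	Shc_p	0	0	
EGF_medium	EGF_medium	1	1	
EGFR	EGFR	0.5	0	
EGFR_EGF	EGFR_EGF	0	0	
EGFR2	EGFR2	0	0	
EGFR2_p	EGFR2_p	0	0	
EGFR2_int	EGFR2_int	0	0	
R_Shc	R_Shc	0	0	
Grb2	Grb2	1	0	
Shc_Grb2	Shc_Grb2	0	0	
SOS	SOS	0.5	0	
Shc_Grb2_SOS	Shc_Grb2_SOS	0	0	
R_Grb2	R_Grb2	0	0	
R_Grb2_SOS	R_Grb2_SOS	0	0	
RasGDP	RasGDP	1	0	
RasGTP	RasGTP	0	0	
RasGTP_Raf1	RasGTP_Raf1	0	0	
MEK	MEK	1	0	
MEK_p	MEK_p	0	0	
ppMEK	ppMEK	0	0	observable:ppMEK
ERK	ERK	1	0	
ERK_p	ERK_p	0	0	
ppERK	doubly phosphorylated ERK	0	0	observable:ppERK
SOS_i	SOS_i	0	0	
ppERK_nuc	ppERK_nuc	0	0	observable:ppERK
GRK	GRK	0.3	0	
TAM_GPR30_p	TAM_GPR30_p	0	0	
bArr1	bArr1	0.5	0	
C_bArr1	C_bArr1	0	0	
GPR30_int	GPR30_int	0	0	
TAM_endo	TAM_endo	0	0	
bArr2	bArr2	0.5	0	
C_bArr2	C_bArr2	0	0	
PI3K	PI3K	0.5	0	
R_PI3K	R_PI3K	0	0	observable:PI3K_active
PI3K_act	PI3K_act	0	0	observable:PI3K_active
PIP3	PIP3	0	0	
PTEN	PTEN	0.3	0	
Akt	Akt	1	0	
Aktm	Aktm	0	0	
PDK1	PDK1	0.5	0	
Aktm_PDK1	Aktm_PDK1	0	0	
Aktm_p	Aktm_p	0	0	
Akt_p	Akt_p	0	0	
JAK	JAK	0.5	0	
R_JAK	R_JAK	0	0	
JAK_act	JAK_act	0	0	
STAT	STAT	1	0	
STAT_p	STAT_p	0	0	
R_STAT	R_STAT	0	0	
STAT_dim	STAT_dim	0	0	
STAT_dim_nuc	STAT_dim_nuc	0	0	
Elk1	Elk1	0.5	0	
ppERK_Elk1	ppERK_Elk1	0	0	observable:ppERK
Elk1_p	Elk1_p	0	0	
fos_mRNA	fos_mRNA	0	0	
Fos	Fos	0	0	
Fos_p	Fos_p	0	0	
Jun	Jun	0.5	0	
AP1	AP1	0	0	
myc_mRNA	myc_mRNA	0	0	
Myc	Myc	0	0	
p53	p53	0.3	0	
ppERK_p53	ppERK_p53	0	0	observable:ppERK
p53_p	p53_p	0	0	
Mdm2	Mdm2	0.2	0	
p53_Mdm2	p53_Mdm2	0	0	
bax_mRNA	bax_mRNA	0	0	
Bax	Bax	0	0	
puma_mRNA	puma_mRNA	0	0	
PUMA	PUMA	0	0	
Bcl2	Bcl2	0.5	0	
Bax_Bcl2	Bax_Bcl2	0	0	
PUMA_Bcl2	PUMA_Bcl2	0	0	
Bax_m	Bax_m	0	0	
CytC_mito	CytC_mito	1	0	
CytC	CytC	0	0	
Apaf	Apaf	0.5	0	
Apop	Apop	0	0	
Casp9	Casp9	0.5	0	
Casp9_act	Casp9_act	0	0	
Casp3	Casp3	0.5	0	
Casp3_act	Casp3_act	0	0	
GEN	GEN	1	1	
mdm2_mRNA	mdm2_mRNA	0	0	
socs_mRNA	socs_mRNA	0	0	
SOCS	SOCS	0	0	
SOCS_JAK	SOCS_JAK	0	0	
MKP	MKP	0.3	0	
MKP_ppERK	MKP_ppERK	0	0	observable:ppERK
PP2A	PP2A	0.3	0	
PP2A_ppMEK	PP2A_ppMEK	0	0	observable:ppMEK
ppERK_total	total doubly phosphorylated ERK (rule readout)	0	0	
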