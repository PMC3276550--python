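# Species registry: name, diffusion constant D (um^2/s, 0 = anchored/non-diffusing),
# and subunit composition in conserved moieties ("moiety:count,...", "-" = none).
# D values follow the published table of diffusible molecules; every species not
# listed there has D = 0. DARPP-32 forms that diffuse are the free, PKAc-bound and
# singly phosphorylated forms; phosphatase- and Cdk5-bound forms are complexes of a
# non-diffusing partner and do not move.
name	D	composition
Da	150	da:1
DaExt	0	da:1
R	0	r:1
DaR	0	da:1,r:1
Gabg	0	ga:1,gbg:1
DaRGabg	0	da:1,r:1,ga:1,gbg:1
DaRGbg	0	da:1,r:1,gbg:1
GaGTP	0	ga:1
GaGDP	0	ga:1
Gbg	0	gbg:1
GabgR	0	r:1,ga:1,gbg:1
AC	0	ac:1
ACGaGTP	0	ac:1,ga:1
ACGaGTP_ATP	0	ac:1,ga:1
ACCa	0	ac:1,ca:1
ACGaGTPCa	0	ac:1,ga:1,ca:1
ACGaGTPCa_ATP	0	ac:1,ga:1,ca:1
ATP	74.7	-
cAMP	86.4	-
AMP	85.5	-
Ca	174.3	ca:1
CaOut	0	ca:1
Calbindin	9.3	calbindin:1
CalbindinCa	9.3	calbindin:1,ca:1
pmca	0	pmca:1
pmcaCa	0	pmca:1,ca:1
ncx	0	ncx:1
ncxCa	0	ncx:1,ca:1
Cam	11	cam:1
CamCa2	11	cam:1,ca:2
CamCa4	11	cam:1,ca:4
PP2B	0	pp2b:1
PP2BCam	0	pp2b:1,cam:1
PP2BCamCa2	0	pp2b:1,cam:1,ca:2
PP2BCamCa4	0	pp2b:1,cam:1,ca:4
CaMKII	3.6	camkii:1
CaMKIIp	3.6	camkii:1
CaMKIICamCa4	3.6	camkii:1,cam:1,ca:4
CaMKIIpCamCa4	3.6	camkii:1,cam:1,ca:4
Complex	0	camkii:2,cam:2,ca:8
pComplex	0	camkii:2,cam:2,ca:8
CaMKIIp_PP1	0	camkii:1,pp1:1
CaMKIIpCamCa4_PP1	0	camkii:1,cam:1,ca:4,pp1:1
PP1	0	pp1:1
PDE1	0	pde1:1
PDE1CamCa4	0	pde1:1,cam:1,ca:4
PDE1CamCa4_cAMP	0	pde1:1,cam:1,ca:4
PDE10	0	pde10:1
PDE10cAMP	0	pde10:1
pPDE10	0	pde10:1
pPDE10cAMP	0	pde10:1
PKAc_PDE10	0	pkac:1,pde10:1
PKAc_PDE10cAMP	0	pkac:1,pde10:1
PKAcAMP4_PDE10	0	pkac:2,pkar:1,pde10:1
PKAcAMP4_PDE10cAMP	0	pkac:2,pkar:1,pde10:1
PKA	0	pkac:2,pkar:1
PKAcAMP2	0	pkac:2,pkar:1
PKAcAMP4	0	pkac:2,pkar:1
R2CcAMP4	0	pkac:1,pkar:1
PKAc	8.1	pkac:1
PKAr	0	pkar:1
D32	10.6	d32:1
D32_PKAc	10.6	d32:1,pkac:1
p34D32	10.6	d32:1
p75D32	10.6	d32:1
p75D32_PKAc	10.6	d32:1,pkac:1
p34D32_PKAcAMP4	0	d32:1,pkac:2,pkar:1
p34D32_PP1	0	d32:1,pp1:1
p34D32_PP2B	0	d32:1,pp2b:1,cam:1,ca:4
p34D32PP1_PP2B	0	d32:1,pp1:1,pp2b:1,cam:1,ca:4
PP1_PP2B	0	pp1:1,pp2b:1,cam:1,ca:4
p34D32_PP2AB56d	0	d32:1,pp2a56:1
p34D32_PP2ABPR72	0	d32:1,pp2a72:1
p34D32PP1_PP2AB56d	0	d32:1,pp1:1,pp2a56:1
p34D32PP1_PP2ABPR72	0	d32:1,pp1:1,pp2a72:1
PP1_PP2AB56d	0	pp1:1,pp2a56:1
PP1_PP2ABPR72	0	pp1:1,pp2a72:1
PP2AB56d	0	pp2a56:1
PP2ABPR72	0	pp2a72:1
pPP2A	0	pp2a56:1
PKAc_PP2AB56d	0	pkac:1,pp2a56:1
PKAcAMP4_PP2AB56d	0	pkac:2,pkar:1,pp2a56:1
CaPP2A	0	pp2a72:1,ca:1
Cdk5	0	cdk5:1
CDK5_D32	0	cdk5:1,d32:1
p75D32_pPP2A	0	d32:1,pp2a56:1
p75D32_PP2AB56d	0	d32:1,pp2a56:1
p75D32_PP2ABPR72	0	d32:1,pp2a72:1
p75D32_CaPP2A	0	d32:1,pp2a72:1,ca:1
GluA1	0	glua1:1
pS845GluA1	0	glua1:1
pS831GluA1	0	glua1:1
pS845pS831GluA1	0	glua1:1
GluA1_PKAc	0	glua1:1,pkac:1
GluA1_PKAcAMP4	0	glua1:1,pkac:2,pkar:1
GluA1_CaMKIICamCa4	0	glua1:1,camkii:1,cam:1,ca:4
GluA1_CaMKIIpCamCa4	0	glua1:1,camkii:1,cam:1,ca:4
GluA1_CaMKIIp	0	glua1:1,camkii:1
pS845GluA1_PP1	0	glua1:1,pp1:1
pS831GluA1_PP1	0	glua1:1,pp1:1
pS845pS831GluA1_PP1	0	glua1:1,pp1:1
pS845pS831GluA1_PP1alt	0	glua1:1,pp1:1
pS845GluA1_PP2B	0	glua1:1,pp2b:1,cam:1,ca:4
pS845pS831GluA1_PP2B	0	glua1:1,pp2b:1,cam:1,ca:4
pS831GluA1_PKAc	0	glua1:1,pkac:1
pS831GluA1_PKAcAMP4	0	glua1:1,pkac:2,pkar:1
pS845GluA1_CaMKIICamCa4	0	glua1:1,camkii:1,cam:1,ca:4
pS845GluA1_CaMKIIpCamCa4	0	glua1:1,camkii:1,cam:1,ca:4
pS845GluA1_CaMKIIp	0	glua1:1,camkii:1
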