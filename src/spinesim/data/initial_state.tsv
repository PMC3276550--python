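# Basal state of the network. All concentrations are nM averaged over the whole
# morphology unless the pool says otherwise.
#
# pool:
#   cytosol   uniform density over the entire morphology (PSD included; only
#             the anchored receptor/G/cyclase pools avoid the PSD)
#   pde10     phosphodiesterase-10 pool; placed per PDE10_distribution
#             (default: dendritic submembrane + spine subvolumes)
#   membrane  plasma-membrane pumps: dendritic submembrane + spine subvolumes
#   pka_avg   morphology-averaged PKA pool (redundant with the anchored table;
#             used only to build pooled well-mixed initial states)
#   psd       value is the LOCAL concentration inside each PSD subvolume
#
# The pump totals (pmca, ncx) are not part of the published tables; they are set
# so that at basal Ca (58.7 nM) the two pumps exactly balance the constitutive
# CaOut->Ca leak, with the extrusion flux split equally between them. The GluA1
# density corresponds to 80 receptors per PSD, within the measured range of
# AMPAR counts per striatal synapse.
species	pool	conc_nM
Ca	cytosol	58.7
CaOut	cytosol	2005230.1
Calbindin	cytosol	145508.3
CalbindinCa	cytosol	14329.0
Da	cytosol	10.0
DaExt	cytosol	1000000.4
ATP	cytosol	1998350.8
cAMP	cytosol	35.6
PDE1	cytosol	3125.4
PDE1CamCa4	cytosol	855.5
PDE10	pde10	800.6
PDE10cAMP	pde10	118.3
pPDE10	pde10	364.3
pPDE10cAMP	pde10	34.0
AMP	cytosol	606.0
CamCa2	cytosol	341.9
Cam	cytosol	4921.5
PP2BCam	cytosol	2359.2
PP2BCamCa2	cytosol	1218.4
PP2BCamCa4	cytosol	8.1
CaMKII	cytosol	11318.4
CaMKIIpCamCa4	cytosol	140.0
CaMKIIp	cytosol	500.0
CaMKIIp_PP1	cytosol	242.7
CaMKIIpCamCa4_PP1	cytosol	8.1
PP1	cytosol	3750.0
PKA	pka_avg	1000.0
PKAcAMP2	pka_avg	160.0
PKAcAMP4	pka_avg	25.0
PKAc	pka_avg	50.0
PKAr	pka_avg	25.0
PP2ABPR72	cytosol	800.0
PP2AB56d	cytosol	630.0
D32	cytosol	36400.0
p34D32_PP1	cytosol	650.0
p34D32PP1_PP2AB56d	cytosol	11.3
Cdk5	cytosol	1088.6
CDK5_D32	cytosol	2057.7
p75D32	cytosol	10370.9
p75D32_PP2ABPR72	cytosol	200.0
p75D32_PP2AB56d	cytosol	200.0
p75D32_CaPP2A	cytosol	25.0
p75D32_pPP2A	cytosol	120.0
pPP2A	cytosol	140.0
CaPP2A	cytosol	33.0
pmca	membrane	1742.1
pmcaCa	membrane	487.0
ncx	membrane	5185.2
ncxCa	membrane	304.4
GluA1	psd	4695.0
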