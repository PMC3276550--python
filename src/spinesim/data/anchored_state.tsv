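# Basal concentrations of the anchored pools, per anchoring site.
#
# spine_nM: local concentration when the pool is anchored in a spine head
#   (receptor/G-protein/cyclase species occupy the two head-cytosol slices;
#   PKA species additionally occupy the PSD slice).
# focal_picoSD: the published surface-density figures (pmol per um^2, "picoSD")
#   for dendritic anchoring, retained for provenance. Focal-dendrite totals are
#   not derived from them: the expected total of each anchored pool is identical
#   in every anchoring configuration (the four-configuration design holds global
#   and local amounts of these molecules equal), so the focal region receives the
#   same expected molecule count as the four spine heads combined.
#
# pool: ac = D1R/G-protein/adenylate-cyclase complex, follows AC_location;
#       pka = PKA holoenzyme/regulatory pool, follows PKA_location.
species	pool	spine_nM	focal_picoSD
R	ac	153.9	20.3
Gabg	ac	8158.3	1012.5
GabgR	ac	1255.5	160.8
GaGTP	ac	8.1	0.0
GaGDP	ac	90.0	12.0
Gbg	ac	43.2	0.0
AC	ac	7428.0	887.6
ACGaGTPCa_ATP	ac	14.0	0.0
ACGaGTP_ATP	ac	114.5	19.0
ACCa	ac	2376.0	259.9
PKA	pka	7050.0	1130.0
PKAcAMP2	pka	925.0	155.0
PKAcAMP4	pka	137.5	30.0
PKAc	pka	300.0	60.0
PKAr	pka	150.0	30.0
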