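species	family	phenotype	wgd_events	n_type1_active	n_type1_inactive	n_type1_lowexpr	s_rnase_status	paper_route_label	provisional	notes
Solanum habrochaites	Solanaceae	TYPE1_SI	1	1	0	0	intact	R1+b	no	single type-1 S-locus despite the Solanaceae WGT
Cucurbita maxima	Cucurbitaceae	TYPE1_SI	1	1	0	0	intact	R1+b	no	single type-1 S-locus
Olea europaea	Oleaceae	TYPE1_SI	1	1	0	0	intact	R1+b	no	single type-1 S-locus
Ziziphus jujube	Rhamnaceae	TYPE1_SI	1	1	0	0	intact	R1+b	no	single type-1 S-locus
Ricinus communis	Euphorbiaceae	TYPE1_SI	1	1	0	0	intact	R1+b	no	single type-1 S-locus
Antirrhinum hispanicum	Plantaginaceae	TYPE1_SI	1	1	0	1	intact	R1+a	no	duplicate S-like locus with a pseudo-SLF and lowly expressed SLF/S-like-RNase
Prunus mume	Rosaceae	TYPE1_SI	1	1	1	0	intact	R1+a	yes	duplicate locus possibly degenerated in the same manner
Citrus clementina	Rutaceae	TYPE1_SI	1	1	1	0	intact	R1+a	yes	duplicate locus possibly degenerated in the same manner
Antirrhinum majus	Plantaginaceae	SC	1	0	1	0	deleted	R2	no	S-RNase deleted; SLFs retained; horticultural selection for SC
Solanum lycopersicum	Solanaceae	SC	1	0	1	0	pseudogene	R2	no	S-RNase inactivated; horticultural selection for SC
Gossypium raimondii	Malvaceae	SC	1	2	0	0	intact	R2	no	duplicate active loci; text label R2 conflicts with duplication=R1 framework
Phaseolus vulgaris	Fabaceae	SC	1	2	0	0	intact	R2	no	duplicate active loci; text label R2 conflicts with duplication=R1 framework
Aquilegia coerulea	Ranunculaceae	SC	1	4	0	0	intact	R2	no	four type-1 S-loci; cryptic SI attributed to inbreeding depression
Brassica oleracea	Brassicaceae	TYPE2_SI	1	0	0	0	na	R3+d	no	no type-1 S-like locus; SRK/SCR system
Primula veris	Primulaceae	TYPE4_SI	0	0	0	0	na	R3+d	no	no type-1 S-like locus; heterostyly supergene
Helianthus annuus	Asteraceae	SSI_OTHER	1	0	0	0	na	R3+d	no	no type-1 S-like locus; sporophytic SI
Papaver somniferum	Papaveraceae	TYPE3_SI	1	0	4	0	na	R1+d	no	four type-1 S-like loci under a PrsS/PrpS system
Coffea canephora	Rubiaceae	GSI_OTHER	0	2	0	0	na	ambiguous	no	GSI of undetermined molecular type with two type-1 S-loci
Petunia hybrida	Solanaceae	TYPE1_SI	1	1	0	0	intact	na	yes	tester genotype; inventory not printed in full
Prunus avium	Rosaceae	TYPE1_SI	1	1	0	0	intact	na	yes	S-locus with SLF- and SFB-type pollen genes
Malus domestica	Rosaceae	TYPE1_SI	1	1	0	0	intact	na	yes	SFBB-type S-locus
Arabidopsis thaliana	Brassicaceae	SC	1	0	0	0	na	R2	yes	SC via the type-2 system (SRK/SCR inactivation), outside the type-1 table
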