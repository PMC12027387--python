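category	gene	cat8_adr1_target	log2fc_rna	log2fc_protein	protein_name
Stress response	CTA1	True	-0.67	-1.59	Catalase A
Stress response	CTT1	False	-1.24	-0.69	Catalase T
Stress response	GPX1	False	-0.73	-0.71	Glutathione peroxidase
Stress response	HSP12	False	-0.89	-0.88	Heat shock protein
Stress response	SIP18	False	-5.50	-5.50	Phospholipid-binding hydrophilin
Stress response	SPG4	False	-1.19	-1.72	Stationary phase protein
Stress response	SSA3	False	-3.64	-1.70	Heat shock protein
Stress response	SSA4	False	-0.66	-0.82	Heat shock protein
Mitochondrial function	ACO1	False	-1.14	-0.85	Aconitate hydratase
Mitochondrial function	CYB2	True	-1.71	-1.74	Cytochrome b
Mitochondrial function	DLD1	True	-1.05	-1.04	D-lactate dehydrogenase
Mitochondrial function	GUT2	True	-1.20	-0.84	Glycerol-3-phosphate dehydrogenase
Mitochondrial function	ICL2	True	-1.25	-2.47	2-methylisocitrate lyase
Mitochondrial function	IDH1	False	-0.59	-0.70	Isocitrate dehydrogenase subunit
Mitochondrial function	IDP2	True	-1.20	-1.32	Isocitrate dehydrogenase
Mitochondrial function	MBR1	False	-0.59	-1.28	Mitochondrial biogenesis regulation protein
Mitochondrial function	NDE2	False	-1.18	-1.28	External NADH-ubiquinone oxidoreductase
Gluconeogenesis	FBP1	True	-1.71	-3.58	Fructose-1,6-bisphosphatase
Gluconeogenesis	PCK1	True	-3.04	-3.35	Phosphoenolpyruvate carboxykinase
Gluconeogenesis	CAT8	False	-0.52	-0.83	Transcription activator
Pentose phosphate pathway	GND2	False	-2.89	-1.57	6-phosphogluconate dehydrogenase
Pentose phosphate pathway	TKL2	False	-2.97	-2.62	Transketolase 2
Peroxisomal function	MLS1	True	-0.85	-1.60	Malate synthase
Peroxisomal function	YPL113C	False	-0.80	-0.66	Glyoxylate reductase
Peroxisomal function	FOX2	True	-0.98	-1.11	3-hydroxyacyl-CoA dehydrogenase and enoyl-CoA hydratase
Other metabolic processes	ACS1	True	-0.89	-1.69	Acetyl-coenzyme A synthetase
Other metabolic processes	ADH2	True	-1.37	-1.11	Alcohol dehydrogenase
Other metabolic processes	AGX1	False	-1.08	-1.98	Alanine-glyoxylate aminotransferase
Other metabolic processes	GUT1	True	-0.80	-0.86	Glycerol kinase
Other metabolic processes	HXT5	False	-4.42	-2.63	Glucose transporter
Other metabolic processes	INO1	False	-1.16	-1.34	Inositol-3-phosphate synthase
Other metabolic processes	NQM1	False	-1.82	-0.88	Transaldolase
Other metabolic processes	RGI2	True	-1.85	-1.38	Respiratory growth induced protein
Other metabolic processes	YKL107W	False	-2.46	-4.24	NADH-dependent aldehyde reductase
Other cellular processes	AMS1	False	-0.78	-0.70	Alpha-mannosidase
Other cellular processes	ATG34	False	-0.70	-0.62	Autophagy-related protein
Other cellular processes	GAC1	False	-0.63	-0.77	Regulatory subunit for Glc7p
Other cellular processes	HBT1	False	-2.28	-2.48	Shmoo tip protein
Other cellular processes	MUB1	False	-0.60	-0.79	MYND-type zinc finger protein
Other cellular processes	FMP45	False	-3.84	-2.06	SUR7 family protein
Other cellular processes	NAT4	False	-0.65	-0.82	Histone-specific N-acetyltransferase
Other cellular processes	PNS1	False	-0.76	-0.83	Putative choline transporter
Other cellular processes	PRY1	False	-0.63	-1.65	Lipid binding protein
Other cellular processes	UIP4	False	-0.64	-0.60	Protein required for nuclear envelope integrity
Other cellular processes	XBP1	False	-1.46	-2.17	Transcriptional repressor induced by stress or starvation
Unknown	YBR241C	False	-0.61	-1.51	Putative transporter
Unknown	YDL199C	False	-0.61	-1.07	Putative transporter
Unknown	YGR067C	True	-0.62	-1.33	Zinc finger protein
Unknown	YGR201C	False	-1.01	-0.60	Putative elongation factor
Unknown	YHR033W	False	-2.94	-2.67	Uncharacterized
Unknown	YKL065W-A	False	-3.16	-3.27	Uncharacterized
Unknown	YNL195C	False	-0.69	-1.00	Uncharacterized
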