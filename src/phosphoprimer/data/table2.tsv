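category	gene	in_signaling	in_polii	function	reduced_sites	enhanced_sites
Signaling	LCB5	True	False	Minor sphingoid long-chain base kinase	S160(2); S164(2)	
Signaling	MDS3	True	False	Negative regulator of early meiotic gene expression	S602(2); S603(2); S698(1); S698(2); S702(1)	S606(1)
Signaling	PKH2	True	False	Serine/threonine protein kinase involved in sphingolipid-mediated signaling pathway that controls endocytosis	S988(3); S990(3); S992(3); T997(2); S1001(2); S1003(1); S1003(2); S1005(2)	
Signaling	RCN1	True	False	Noncompetitive calcineurin inhibitor involved in calcium-mediated signaling	S113(2); S117(2); S117(1)	
Signaling	RTC1	True	False	Subunit of SEACAT inhibiting the TORC1 inhibitory role of the Iml1p/SEACIT subcomplex	S1129(2); S1133(2)	S1133(1)
Signaling	SIP1	True	False	One of three alternate beta-subunits of the Snf1p kinase complex	S377(2); S381(2); S385(1)	
Signaling	SIP2	True	False	One of three alternate beta subunits of the Snf1 kinase complex	S66(2); S70(2); S133(2); S133(3); S136(2); S136(3); S137(3)	S137(1)
Signaling	SLN1	True	False	Histidine phosphotransfer kinase	S386(2); S390(2)	
Pol II transcription	ASH1	False	True	Component of the Rpd3L histone deacetylase complex	T87(2); S91(2); S91(3); T104(3); S108(3)	
Pol II transcription	DCP2	False	True	Catalytic subunit of Dcp1p-Dcp2p decapping enzyme complex	S724(2); S725(1); S725(2); S728(2); S729(2)	S729(1)
Pol II transcription	EAF7	False	True	Subunit of nuclear NuA4 histone acetyltransferase complex	S393(1); S393(2); T396(2); S397(2)	T396(1); S397(1)
Pol II transcription	HAA1	False	True	Transcriptional activator involved in adaptation to weak acid stress	S413(2); S417(2)	
Pol II transcription	NOT3	False	True	Component of the CCR4-NOT core complex	S303(2); S304(2); T305(2); S442(2); S442(3); S442(1); S446(2); S446(3); S450(2); S450(3); T454(3)	S307(1)
Pol II transcription	NOT5	False	True	Component of the CCR4-NOT core complex	S271(2); S273(3); S275(2); S275(3); S302(1); S302(2); T306(2)	
Pol II transcription	ROX3	False	True	Subunit of the RNA polymerase II mediator complex	S200(1); S200(3); T204(3)	T204(1)
Pol II transcription	SGF29	False	True	Component of the HAT/Core module of the SAGA, SLIK, and ADA complexes	S83(2); S83(1)	T87(1)
Pol II transcription	SMY2	False	True	ER membrane protein involved in ER-to-Golgi vesicle-mediated transport	S80(2); S80(3); T82(3); S83(2); S83(3); S84(2); S84(3)	
Pol II transcription	SPT20	False	True	Subunit of the SAGA transcriptional regulatory complex	S593(1); S593(2); S595(1); S595(2); T597(2)	
Pol II transcription	STB3	False	True	Transcription activator involved in positive regulation of transcription by glucose	S337(1); S337(2); S341(2)	
Pol II transcription	TAF5	False	True	Subunit of SAGA and transcription factor TFIID complex	S411(2); S411(3); S411(1); S414(2); S414(3); S415(2); S415(3)	S414(1); S415(1)
Pol II transcription	WAR1	False	True	Transcription factor; binds to a weak acid response element to induce transcription of PDR12 and FUN34	S124(2); T128(2)	
Polarized growth	AIM21	False	False	Subunit of a complex associating with actin filaments	S145(2); S149(2)	
Polarized growth	AKL1	False	False	Ser/Thr protein kinase negatively regulating endocytosis	S403(2); S407(2)	
Polarized growth	APL3	False	False	Alpha-adaptin	S723(2)	T727(1)
Polarized growth	BCK1	True	False	MAPKKK in the PKC1 signaling pathway	S505(2); S509(2)	
Polarized growth	BNI5	False	False	Linker protein for recruitment of myosin to the bud neck	S270(1); S270(2); S273(2); T274(2)	T274(1)
Polarized growth	BOI1	False	False	Protein involved in polar growth	S574(2); S574(1); S578(2)	
Polarized growth	BOI2	False	False	Protein involved in polar growth	T612(2); S615(2); S615(3); S616(3); S617(2); S617(3); S619(3); S620(3); S637(3); S639(2); S639(3); T641(3); S642(2); S642(3); S643(3)	
Polarized growth	DSF2	False	False	Deletion suppressor of mpt5 mutation; relocalizes from bud neck to cytoplasm upon DNA replication stress	S391(2); S395(2)	
Polarized growth	KRE6	False	False	Glucosyl hydrolase required for beta-1,6-glucan biosynthesis	S108(2); S108(1); S112(2)	
Polarized growth	LSB3	False	False	Protein involved in actin cortical patch localization	S377(2); T393(2); S397(2); S397(3)	S381(1)
Polarized growth	PAL1	False	False	Protein of unknown function thought to be involved in endocytosis	S186(1); S186(2); S186(3); S189(2); S189(3); S190(2); S190(3)	
Polarized growth	PRK1	False	False	Ser/Thr protein kinase regulating the organization and function of the actin cytoskeleton	S533(1); S533(3); T537(3); S540(3)	T537(2); S540(2)
Polarized growth	SEC31	False	False	Component of the Sec13p-Sec31p complex of the COPII vesicle coat	S988(2); S988(3); S988(1); S992(3)	S992(1)
Polarized growth	SKG1	False	False	Transmembrane protein with a role in cell wall polymer composition	T212(2); T212(3); S215(2); S215(3); S216(2); S216(3)	
Polarized growth	SLA1	False	False	Cytoskeletal protein binding protein	S473(3); S476(3); S477(3)	
Polarized growth	SMY1	False	False	Kinesin-like myosin passenger-protein	S566(2); S566(1); S570(2)	S570(1)
Polarized growth	TAO3	False	False	Component of the RAM signaling network involved in regulation of Ace2p activity and cellular morphogenesis	S318(2)	S322(1)
Polarized growth and cell cycle	BIK1	False	False	Microtubule-associated protein	T85(1); T85(2); T85(3); S86(1); S86(2); S86(3); T89(2); T89(3); T90(3)	
Polarized growth and cell cycle	BNI1	False	False	Formin; polarisome component	S75(1); S75(2); S79(2); S257(2); S1334(1); S1334(3); T1337(3); S1338(1); S1338(2); S1338(3)	
Polarized growth and cell cycle	BNR1	False	False	Formin nucleating the formation of linear actin filaments	S604(2); S604(3); S608(3)	
Polarized growth and cell cycle	BUD3	False	False	Guanine nucleotide exchange factor (GEF) for Cdc42p	T1026(3); S1029(3); S1030(3)	
Polarized growth and cell cycle	CDC55	True	False	Regulatory subunit B of protein phosphatase 2A	S145(1); S145(2); S149(2)	
Polarized growth and cell cycle	CYK3	False	False	SH3-domain protein located in the bud neck and cytokinetic actin ring	S118(2); S122(2)	S122(1)
Polarized growth and cell cycle	GIN4	True	False	Protein kinase involved in bud growth and assembly of the septin ring	S947(3); S949(3)	S950(1); S951(1)
Polarized growth and cell cycle	HSL1	True	False	Ser/thr protein kinase involved in the G2/M transition	S1325(2); S1328(2); S1329(2)	
Polarized growth and cell cycle	KAR9	True	False	Spindle pole protein	T586(2); T590(2)	
Polarized growth and cell cycle	KIN4	True	False	Serine/threonine protein kinase inhibiting the mitotic exit network (MEN) when the spindle position checkpoint (SPOC) is activated	S384(2); S384(3); S388(2); S388(3)	
Polarized growth and cell cycle	STE20	True	False	MAP kinase kinase kinase kinase involved in pheromone signaling, bud site selection, regulation of mitotic exit and others	S524(1); S524(2); T528(2)	
Cell cycle	ACE2	True	True	Transcription factor required for septum destruction after cytokinesis	S249(3); S253(3)	S253(1)
Cell cycle	BCK2	False	False	Serine/threonine-rich protein involved in PKC1 signaling pathway	S575(2); T579(2)	
Cell cycle	CDC4	False	False	F-box protein required for both the G1/S and G2/M phase transitions	S71(2); S71(3); S74(2); S74(3); T75(2); T75(3)	S74(1); T75(1)
Cell cycle	IGO1	False	False	Protein required for initiation of the G0 program	S7(1); S11(2)	
Cell cycle	LTE1	False	False	Protein similar to GDP/GTP exchange factors	S850(2); S854(2)	S854(1)
Cell cycle	MCM3	False	False	Protein involved in DNA replication	S777(2); S777(1); S779(2); S779(3)	S779(1); S781(1)
Cell cycle	RFM1	True	True	Component of the Sum1p-Rfm1p-Hst1p complex	S211(2); S215(2)	
Cell cycle	SLD2	False	False	DNA-binding subunit of the DNA replication preinitiation complex	S124(2); S128(2)	S128(1)
Cell cycle	VHS2	False	False	Regulator of septin dynamics	S84(2)	S88(1)
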