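protein	description	category	fold_decrease	p_value
DmsA	Dimethyl sulfoxide reductase	Anaerobic response and FeS-cluster-containing proteins	21.5	1.90E-03
FrdA	Fumarate reductase flavoprotein subunit	Anaerobic response and FeS-cluster-containing proteins	4.3	9.34E-05
FrdB	Fumarate reductase iron-sulfur subunit	Anaerobic response and FeS-cluster-containing proteins	6.5	2.09E-05
FumB	Fumarate hydratase class I, anaerobic	Anaerobic response and FeS-cluster-containing proteins	4.8	2.79E-03
GlpA	Anaerobic glycerol-3-phosphate dehydrogenase subunit A	Anaerobic response and FeS-cluster-containing proteins	24.7	6.51E-04
GlpB	Anaerobic glycerol-3-phosphate dehydrogenase subunit B	Anaerobic response and FeS-cluster-containing proteins	4.6	3.39E-03
MiaB	tRNA-2-methylthio-N(6)-dimethylallyladenosine synthase	Anaerobic response and FeS-cluster-containing proteins	9.1	1.56E-02
NarG	Respiratory nitrate reductase 1 alpha chain	Anaerobic response and FeS-cluster-containing proteins	6.2	9.52E-02
NarH	Respiratory nitrate reductase 1 beta chain	Anaerobic response and FeS-cluster-containing proteins	11.4	1.09E-02
NirB	Nitrite reductase (NADH) large subunit	Anaerobic response and FeS-cluster-containing proteins	37.4	2.96E-04
PreT	NAD-dependent dihydropyrimidine dehydrogenase subunit	Anaerobic response and FeS-cluster-containing proteins	15.4	1.46E-06
SdaB	L-Serine dehydratase 2	Anaerobic response and FeS-cluster-containing proteins	31.1	1.13E-01
TdcG	L-Serine/threonine dehydratase	Anaerobic response and FeS-cluster-containing proteins	12.3	3.04E-05
GrcA	Autonomous glycyl radical cofactor	Glycyl radical proteins	5.2	1.88E-03
TdcE	PFL-like enzyme (ketobutyrate formate lyase)	Glycyl radical proteins	60.6	2.89E-04
LamB	Maltoporin	Maltose and trehalose	16.5	8.15E-03
MalE	Maltose-binding periplasmic protein	Maltose and trehalose	15.0	1.34E-03
MalP	Maltodextrin phosphorylase	Maltose and trehalose	4.5	3.21E-05
MalQ	4-Alpha-glucanotransferase	Maltose and trehalose	5.5	1.44E-03
TreB	PTS trehalose-specific EIIBC component	Maltose and trehalose	36.2	4.38E-03
TreC	Trehalose-6-phosphate hydrolase	Maltose and trehalose	9.5	1.53E-04
FadL	Long-chain fatty acid transport protein	Porins	10.4	7.97E-03
OmpF	Outer membrane protein F	Porins	11.5	2.18E-02
Tsx	Nucleoside-specific channel-forming protein	Porins	5.3	2.82E-03
DeaD	ATP-dependent RNA helicase	Replication and cell division	13.9	1.40E-02
MnmG	tRNA uridine 5-carboxymethylaminomethyl modification	Replication and cell division	7.6	2.89E-02
MurA	UDP-N-acetylglucosamine 1-carboxyvinyltransferase	Replication and cell division	3.6	2.89E-03
ParE	DNA topoisomerase 4 subunit B	Replication and cell division	6.1	2.10E-02
RimO	Ribosomal protein S12 methylthiotransferase	Replication and cell division	3.1	1.52E-02
RplD	50S ribosomal protein L4	Replication and cell division	3.2	1.78E-02
RplP	50S ribosomal protein L16	Replication and cell division	4.3	2.28E-02
RplT	50S ribosomal protein L20	Replication and cell division	3.4	2.78E-02
RplU	50S ribosomal protein L21	Replication and cell division	3.3	4.12E-03
RplY	50S ribosomal protein L25	Replication and cell division	4.0	3.47E-02
RpmB	50S ribosomal protein L28	Replication and cell division	3.2	1.86E-02
TtcA	tRNA 2-thiocytidine biosynthesis protein	Replication and cell division	8.7	2.84E-02
rfbB	dTDP-glucose 4,6-dehydratase 1	LPS biosynthesis	3.8	3.06E-05
RfbD	dTDP-4-dehydrorhamnose reductase	LPS biosynthesis	4.3	1.17E-02
AnsB	L-Asparaginase 2	Aspartate/asparagine catabolism	7.8	1.19E-02
AsnA	Aspartate-ammonia ligase	Aspartate/asparagine catabolism	7.1	3.30E-03
AspA	Aspartate ammonia-lyase	Aspartate/asparagine catabolism	5.7	1.09E-05
GarD	D-Galactarate dehydratase	Glyoxylate degradation	3.8	3.55E-03
GarR	2-Hydroxy-3-oxopropionate reductase	Glyoxylate degradation	8.7	2.70E-03
YdhQ	Uncharacterized protein YdhQ	Uncharacterized	5.5	9.51E-04
YgeV	Uncharacterized sigma54-dependent transcriptional regulator	Uncharacterized	3.4	2.01E-03
YjjI	Uncharacterized protein YjjI	Uncharacterized	6.2	3.36E-03
FtnA	Bacterial nonheme ferritin	Others	5.2	1.83E-02
GatZ	D-Tagatose-1,6-bisphosphate aldolase subunit	Others	4.1	2.37E-03
GuaC	GMP reductase	Others	4.7	1.72E-03
HupA	DNA-binding protein HU-alpha	Others	4.1	4.90E-03
HypB	Hydrogenase isoenzymes nickel incorporation protein	Others	7.1	5.01E-02
NanA	N-Acetylneuraminate lyase	Others	3.4	3.08E-03
PepE	Peptidase E	Others	3.9	5.16E-04
RpoS	RNA polymerase sigma factor	Others	4.9	3.77E-04
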