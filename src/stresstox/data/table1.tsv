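protein	description	category	fold_increase	p_value
AhpC	Alkyl hydroperoxide reductase subunit C	Oxidative stress defense	4.1	1.86E-05
AhpF	Alkyl hydroperoxide reductase subunit F	Oxidative stress defense	2.6	1.30E-04
KatE	Catalase HPII	Oxidative stress defense	4.8	4.65E-02
MarR	Multiple antibiotic resistance protein	Oxidative stress defense	9.4	3.89E-03
OsmC	Peroxiredoxin	Oxidative stress defense	4.4	2.74E-03
SodA	Superoxide dismutase (Mn)	Oxidative stress defense	5.0	3.58E-02
GrxB	Glutaredoxin-2	Glutathione	7.5	4.94E-04
GshB	Glutathione synthetase	Glutathione	8.4	1.44E-02
Gss	Glutathionylspermidine synthetase/amidase	Glutathione	3.4	5.99E-04
GstA	Glutathione S-transferase	Glutathione	4.2	1.14E-02
YghU	Disulfide-bond oxidoreductase	Glutathione	6.5	1.01E-03
YqjG	Glutathionyl-hydroquinone reductase	Glutathione	3.7	5.01E-04
GadC	Glutamate/gamma-aminobutyrate antiporter	Low-MW compound accumulation	5.5	4.87E-03
GltB	Glutamate synthase (NADPH) large chain	Low-MW compound accumulation	2.8	9.58E-02
OtsA	alpha,alpha-Trehalose-phosphate synthase (UDP forming)	Low-MW compound accumulation	4.6	1.48E-03
CbpA	Curved DNA-binding protein	Chaperones and proteases	3.4	3.89E-03
ClpB	Chaperone protein	Chaperones and proteases	2.8	3.78E-05
Dcp	Periplasmic serine endoprotease	Chaperones and proteases	3.1	1.44E-05
DegP	Periplasmic serine endoprotease	Chaperones and proteases	5.7	1.08E-05
HchA	Molecular chaperone Hsp31 and glyoxalase 3	Chaperones and proteases	9.6	2.72E-03
HslO	33-kDa chaperonin	Chaperones and proteases	4.3	2.23E-02
PepB	Peptidase B	Chaperones and proteases	5.2	2.45E-05
EntB	Enterobactin synthase component B	Metal homeostasis	37.2	1.17E-05
EntE	Enterobactin synthase component E	Metal homeostasis	8.5	1.19E-03
EntF	Enterobactin synthase component F	Metal homeostasis	23.1	6.64E-03
MoaB	Molybdenum cofactor biosynthesis protein B	Metal homeostasis	9.2	1.40E-06
SufB	FeS cluster assembly protein	Metal homeostasis	5.9	4.04E-04
SufD	FeS cluster assembly protein	Metal homeostasis	5.2	6.42E-03
SufS	Cysteine desulfurase	Metal homeostasis	5.6	1.86E-03
Ahr	Aldehyde reductase	Aldehyde detoxification	8.5	1.82E-03
AldB	Aldehyde dehydrogenase B	Aldehyde detoxification	7.9	6.58E-04
DkgA	2,5-Diketo-D-gluconic acid reductase A	Aldehyde detoxification	41.1	6.46E-04
YahK	Aldehyde reductase	Aldehyde detoxification	3.6	3.90E-02
YghA	Uncharacterized oxidoreductase	Aldehyde detoxification	4.3	1.87E-02
YqhD	Alcohol dehydrogenase	Aldehyde detoxification	34.8	6.11E-04
AceA	Isocitrate lyase	Central carbon metabolism and energy production	5.1	3.15E-02
AceB	Malate synthase A	Central carbon metabolism and energy production	6.4	6.52E-03
AcnA	Aconitate hydratase 1	Central carbon metabolism and energy production	8.0	7.53E-03
Acs	Acetyl-coenzyme A synthetase	Central carbon metabolism and energy production	5.6	2.60E-02
FbaB	Fructose-bisphosphate aldolase class 1	Central carbon metabolism and energy production	6.9	2.82E-03
FumC	Fumarate hydratase class II	Central carbon metabolism and energy production	38.4	1.49E-05
GltA	Citrate synthase	Central carbon metabolism and energy production	3.3	1.51E-02
Mdh	Malate dehydrogenase	Central carbon metabolism and energy production	4.0	3.12E-04
MtlA	PTS mannitol-specific EIICBA component	Central carbon metabolism and energy production	4.1	4.68E-04
PfkB	ATP-dependent 6-phosphofructokinase isozyme 2	Central carbon metabolism and energy production	3.6	2.00E-02
Ppk	Polyphosphate kinase	Central carbon metabolism and energy production	3.5	6.31E-04
PoxB	Pyruvate oxidase (ubiquinone reducing)	Central carbon metabolism and energy production	10.9	1.24E-02
Sad	Succinate semialdehyde dehydrogenase	Central carbon metabolism and energy production	6.8	1.02E-02
TalA	Transaldolase A	Central carbon metabolism and energy production	4.7	1.06E-02
TktB	Transketolase 2	Central carbon metabolism and energy production	5.3	2.03E-02
Zwf	Glucose-6-phosphate 1-dehydrogenase	Central carbon metabolism and energy production	3.6	4.46E-04
NfsA	Oxygen-insensitive NADPH nitroreductase	Nitrocompound detoxification	12.8	5.64E-06
NfnB	Oxygen-insensitive NAD(P)H nitroreductase	Nitrocompound detoxification	14.8	7.03E-06
AstC	Succinylornithine transaminase	Amino acid biosynthesis	4.1	4.80E-02
HisB	Histidine biosynthesis bifunctional protein	Amino acid biosynthesis	5.5	4.59E-03
HisC	Histidinol-phosphate aminotransferase	Amino acid biosynthesis	5.2	2.21E-02
HisD	Histidinol dehydrogenase	Amino acid biosynthesis	3.8	2.90E-03
HisG	ATP phosphoribosyltransferase	Amino acid biosynthesis	8.0	9.55E-05
IlvB	Acetolactate synthase isozyme 1 large subunit	Amino acid biosynthesis	3.9	3.32E-02
LysC	Lysine-sensitive aspartokinase 3	Amino acid biosynthesis	3.0	4.23E-04
PheA	P-protein	Amino acid biosynthesis	3.4	1.13E-02
TrpB	Tryptophan synthase beta chain	Amino acid biosynthesis	2.7	6.73E-04
YecD	Isochorismatase family protein	Amino acid biosynthesis	7.2	5.35E-04
FolE	GTP cyclohydrolase 1	Folate metabolism	3.1	1.31E-04
PanB	3-Methyl-2-oxobutanoate hydroxymethyltransferase	Folate metabolism	3.5	8.48E-03
YbgI	Putative GTP cyclohydrolase 1 type 2	Folate metabolism	3.1	7.58E-03
YgfZ	tRNA-modifying protein	Folate metabolism	4.9	2.44E-03
UidA	Beta-glucuronidase	beta-D-Glucuronide and D-glucuronate degradation	5.6	1.78E-03
UxaC	Uronate isomerase	beta-D-Glucuronide and D-glucuronate degradation	12.8	8.36E-05
UxuA	Mannonate dehydratase	beta-D-Glucuronide and D-glucuronate degradation	4.1	1.00E-02
YbjP	Uncharacterized lipoprotein	Uncharacterized	4.0	4.46E-02
YdhJ	Uncharacterized protein	Uncharacterized	3.5	1.06E-02
YeiR	Uncharacterized protein	Uncharacterized	6.4	1.90E-02
YhbW	Uncharacterized protein	Uncharacterized	77.1	4.18E-08
YjhC	Uncharacterized oxidoreductase	Uncharacterized	23.8	4.43E-03
YncE	Uncharacterized protein	Uncharacterized	9.5	1.31E-02
Add	Adenosine deaminase	Others	3.5	2.75E-04
Amn	AMP nucleosidase	Others	5.5	6.10E-06
AnmK	Anhydro-N-acetylmuramic acid kinase	Others	3.2	2.39E-04
Cfa	Cyclopropane-fatty-acyl-phospholipid synthase	Others	4.2	4.81E-04
CodA	Cytosine deaminase	Others	3.2	2.99E-02
CurA	NADPH-dependent curcumin reductase	Others	4.1	3.97E-03
DcyD	D-Cysteine desulfhydrase	Others	4.4	3.35E-03
EmrA	Multidrug export protein	Others	4.5	1.26E-02
GhrA	Glyoxylate/hydroxypyruvate reductase A	Others	4.8	5.56E-04
HdhA	7-Alpha-hydroxysteroid dehydrogenase	Others	10.4	3.08E-04
HemB	Delta-aminolevulinic acid dehydratase	Others	9.0	3.32E-03
LysU	Lysine-tRNA ligase, heat inducible	Others	3.8	1.18E-05
MdaB	Modulator of drug activity B	Others	8.4	1.93E-05
MetG	Methionine-tRNA ligase	Others	2.7	4.19E-05
MnmA	tRNA-specific 2-thiouridylase	Others	2.8	1.60E-02
TorA	Trimethylamine-N-oxide reductase 1	Others	8.1	5.48E-03
YadG	Uncharacterized ABC transporter ATP-binding protein	Others	8.9	3.26E-04
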