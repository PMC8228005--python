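Symbol	Full Name	SSC	Location
SASH1	SAM and SH3 domain containing 1	1	17306364..17663117
NAV2	Neuron navigator 2	2	39263939..40083539
DTWD2	DTW domain containing 2	2	122680254..122937002
SIL1	SIL1 nucleotide exchange factor	2	140884170..141118201
A2ML1	Alpha-2-macroglobulin like 1	5	62603260..62648170
HS6ST3	Heparan sulfate 6-O-sulfotransferase 3	11	65516180..66193410
MBNL2	muscle blind-like splicing regulator 2	11	66481923..66641653
MSI2	Musashi RNA binding protein 2	12	33537163..33974845
ROBO2	Roundabout guidance receptor 2	13	177365712..179040027
RIMBP2	RIMS binding protein 2	14	24394793..24722237
MSI1	Musashi RNA binding protein 1	14	40331371..40356793
SVOP	SV2 related protein	14	41829649..41931359
SART3	Spliceosome associated factor 3, U4/U6 recycling protein	14	42223752..42259992
SGSM1	Small G protein signaling modulator 1	14	42882101..42974755
CDH23	Cadherin related 23	14	74267547..74734623
PID1	Phosphotyrosine interaction domain containing 1	15	130080821..130215548
DNER	Delta/notch-like EGF repeat containing	15	130414159..130754043
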