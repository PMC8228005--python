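Symbol	Full Name	SSC	Location
RBFOX1	RNA binding fox-1 homolog 1	3	34938703..37209772
A2ML1	Alpha-2-macroglobulin like 1	5	62603260..62648170
NUMB	NUMB endocytic adaptor protein	7	96624270..96798690
KCNK2	Potassium two pore domain channel subfamily K member 2	9	128429232..128659662
DTL	Denticleless E3 ubiquitin protein ligase homolog	9	131225840..131275426
FLT1	FMs-related receptor tyrosine kinase 1	11	5620698..5797095
MSI2	Musashi RNA binding protein 2	12	33537163..33974845
ZNF385D	Zinc finger protein 385D	13	8234734..9214628
SCN10A	Sodium voltage-gated channel alpha subunit 10	13	23481537..23570454
SCN11A	Sodium voltage-gated channel alpha subunit 11	13	23602378..23692281
WDR48	WD repeat domain 48	13	23735566..23786312
TTC21A	Tetratricopeptide repeat domain 21A	13	23797518..23830334
ROBO2	Roundabout guidance receptor 2	13	177365712..179040027
MYO10	Myosin X	16	5907111..6145485
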