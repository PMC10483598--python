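{
"ABL1": [
"A25G",
"R38H",
"N51I",
"D64L",
"C77K"
],
"AKT1": [
"E17K",
"L52R"
],
"ALK": [
"N99F",
"D112P",
"C125S",
"Q138T",
"E151W"
],
"APC": [
"R1450*",
"R876*",
"E1309FS",
"Q1367*",
"T1556FS"
],
"AR": [
"C173V",
"Q186A",
"E199R",
"G212N",
"H225D"
],
"ARID1A": [
"Q210N",
"E223D",
"G236C",
"H249Q",
"I262E"
],
"ATM": [
"E247Q",
"G260E",
"H273G",
"I286H",
"L299I"
],
"BRAF": [
"V600E",
"V600K",
"G469A",
"D594G"
],
"BRCA1": [
"H321K",
"I334M",
"L347F",
"K360P",
"M373S"
],
"BRCA2": [
"I358P",
"L371S",
"K384T",
"M397W",
"F410Y"
],
"CCND1": [
"L395W",
"K408Y",
"M421V",
"F434A",
"P447R"
],
"CCND2": [
"K432A",
"M445R",
"F458N",
"P471D",
"S484C"
],
"CCNE1": [
"M469D",
"F482C",
"P495Q",
"S508E",
"T521G"
],
"CDH1": [
"F506E",
"P519G",
"S532H",
"T545I",
"W558L"
],
"CDK4": [
"P543I",
"S556L",
"T569K",
"W582M",
"Y595F"
],
"CDK6": [
"S580M",
"T593F",
"W606P",
"Y619S",
"V632T"
],
"CDKN2A": [
"R80*",
"H83Y",
"D108Y",
"P114L"
],
"CTNNB1": [
"S45F",
"T41A",
"S37F",
"D32Y"
],
"EGFR": [
"L858R",
"E746_A750DEL",
"T790M",
"G719A",
"L861Q"
],
"ERBB2": [
"S310F",
"L755S",
"V777L",
"Y772_A775DUP"
],
"ESR1": [
"D538G",
"Y537S",
"E380Q"
],
"EZH2": [
"R802L",
"N815K",
"D828M",
"C841F",
"Q854P"
],
"FBXW7": [
"R465C",
"R505C",
"R479Q"
],
"FGFR1": [
"D76T",
"C89W",
"Q102Y",
"E115V",
"G128A"
],
"FGFR2": [
"C113V",
"Q126A",
"E139R",
"G152N",
"H165D"
],
"FGFR3": [
"S249C",
"Y373C",
"R248C"
],
"GATA3": [
"E187Q",
"G200E",
"H213G",
"I226H",
"L239I"
],
"GNA11": [
"Q209L",
"R183C"
],
"GNAQ": [
"Q209P",
"Q209L"
],
"GNAS": [
"R201C",
"R201H"
],
"HRAS": [
"Q61R",
"G12S",
"G13R"
],
"IDH1": [
"R132H",
"R132C",
"R132G"
],
"IDH2": [
"M409D",
"F422C",
"P435Q",
"S448E",
"T461G"
],
"JAK2": [
"F446E",
"P459G",
"S472H",
"T485I",
"W498L"
],
"JAK3": [
"P483I",
"S496L",
"T509K",
"W522M",
"Y535F"
],
"KIT": [
"D816V",
"W557_K558DEL",
"V559D"
],
"KRAS": [
"G12D",
"G12V",
"G12C",
"G13D",
"Q61H",
"A146T"
],
"MAP2K1": [
"K57N",
"Q56P",
"P124L"
],
"MET": [
"D1228N",
"Y1230C",
"X1010SPLICE"
],
"MLH1": [
"V668C",
"A681Q",
"R694E",
"N707G",
"D720H"
],
"MYC": [
"A705G",
"R718H",
"N731I",
"D744L",
"C757K"
],
"NF1": [
"R742L",
"N755K",
"D768M",
"C781F",
"Q794P"
],
"NOTCH1": [
"N779F",
"D792P",
"C805S",
"Q818T",
"E831W"
],
"NRAS": [
"Q61R",
"Q61K",
"G12D",
"G13R"
],
"PDGFRA": [
"C53V",
"Q66A",
"E79R",
"G92N",
"H105D"
],
"PIK3CA": [
"E545K",
"H1047R",
"E542K",
"N345K",
"C420R"
],
"PTEN": [
"R130G",
"R233*",
"R130Q",
"K267FS"
],
"RAF1": [
"G164H",
"H177I",
"I190L",
"L203K",
"K216M"
],
"RB1": [
"H201K",
"I214M",
"L227F",
"K240P",
"M253S"
],
"RET": [
"I238P",
"L251S",
"K264T",
"M277W",
"F290Y"
],
"SMAD4": [
"R361H",
"R361C",
"D351H"
],
"SMO": [
"K312A",
"M325R",
"F338N",
"P351D",
"S364C"
],
"STK11": [
"M349D",
"F362C",
"P375Q",
"S388E",
"T401G"
],
"TP53": [
"R175H",
"R248Q",
"R273H",
"R282W",
"G245S",
"Y220C"
],
"VHL": [
"R167Q",
"L178P",
"S65L"
]
}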