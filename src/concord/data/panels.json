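{
 "panels": [
  {
   "name": "ctdna_v1_53",
   "effective_from": "1900-01-01",
   "effective_to": "2015-02-01",
   "genes": [
    "ABL1",
    "AKT1",
    "ALK",
    "APC",
    "AR",
    "ARID1A",
    "ATM",
    "BRAF",
    "BRCA1",
    "BRCA2",
    "CCND1",
    "CCND2",
    "CCNE1",
    "CDH1",
    "CDK4",
    "CDK6",
    "CDKN2A",
    "CTNNB1",
    "EGFR",
    "ERBB2",
    "ESR1",
    "EZH2",
    "FBXW7",
    "FGFR1",
    "FGFR2",
    "FGFR3",
    "GATA3",
    "GNA11",
    "GNAQ",
    "GNAS",
    "HRAS",
    "IDH1",
    "IDH2",
    "JAK2",
    "JAK3",
    "KIT",
    "KRAS",
    "MAP2K1",
    "MET",
    "MLH1",
    "MYC",
    "NF1",
    "NOTCH1",
    "NRAS",
    "PDGFRA",
    "PIK3CA",
    "PTEN",
    "RB1",
    "RET",
    "SMAD4",
    "SMO",
    "TP53",
    "VHL"
   ],
   "amp_genes": [
    "EGFR",
    "ERBB2",
    "MET"
   ]
  },
  {
   "name": "ctdna_v2_55",
   "effective_from": "2015-02-01",
   "effective_to": "2100-01-01",
   "genes": [
    "ABL1",
    "AKT1",
    "ALK",
    "APC",
    "AR",
    "ARID1A",
    "ATM",
    "BRAF",
    "BRCA1",
    "BRCA2",
    "CCND1",
    "CCND2",
    "CCNE1",
    "CDH1",
    "CDK4",
    "CDK6",
    "CDKN2A",
    "CTNNB1",
    "EGFR",
    "ERBB2",
    "ESR1",
    "EZH2",
    "FBXW7",
    "FGFR1",
    "FGFR2",
    "FGFR3",
    "GATA3",
    "GNA11",
    "GNAQ",
    "GNAS",
    "HRAS",
    "IDH1",
    "IDH2",
    "JAK2",
    "JAK3",
    "KIT",
    "KRAS",
    "MAP2K1",
    "MET",
    "MLH1",
    "MYC",
    "NF1",
    "NOTCH1",
    "NRAS",
    "PDGFRA",
    "PIK3CA",
    "PTEN",
    "RAF1",
    "RB1",
    "RET",
    "SMAD4",
    "SMO",
    "STK11",
    "TP53",
    "VHL"
   ],
   "amp_genes": [
    "AR",
    "BRAF",
    "CCND1",
    "CCND2",
    "CCNE1",
    "CDK4",
    "CDK6",
    "EGFR",
    "ERBB2",
    "FGFR1",
    "FGFR2",
    "KIT",
    "KRAS",
    "MET",
    "MYC",
    "PIK3CA"
   ]
  }
 ]
}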