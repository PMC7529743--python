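name,cid,smiles
diallyl disulfide,16590,C=CCSSCC=C
diallyl trisulfide,16315,C=CCSSSCC=C
allicin,65036,C=CCSS(=O)CC=C
alliin,87310,C=CCS(=O)CC(N)C(=O)O
theobromine,5429,CN1C=NC2=C1C(=O)NC(=O)N2C
caffeine,2519,CN1C=NC2=C1C(=O)N(C)C(=O)N2C
theophylline,2153,CN1C2=C(C(=O)N(C)C1=O)NC=N2
catechin,9064,OC1CC2=C(O)C=C(O)C=C2OC1C1=CC=C(O)C(O)=C1
quercetin,5280343,O=C1C(O)=C(OC2=CC(O)=CC(O)=C12)C1=CC=C(O)C(O)=C1
kaempferol,5280863,O=C1C(O)=C(OC2=CC(O)=CC(O)=C12)C1=CC=C(O)C=C1
gallic acid,370,OC(=O)C1=CC(O)=C(O)C(O)=C1
caffeic acid,689043,OC(=O)C=CC1=CC=C(O)C(O)=C1
ferulic acid,445858,COC1=CC(C=CC(O)=O)=CC=C1O
p-coumaric acid,637542,OC(=O)C=CC1=CC=C(O)C=C1
ascorbic acid,54670067,OCC(O)C1OC(=O)C(O)=C1O
citric acid,311,OC(=O)CC(O)(CC(O)=O)C(O)=O
malic acid,525,OC(CC(O)=O)C(O)=O
oxalic acid,971,OC(=O)C(O)=O
succinic acid,1110,OC(=O)CCC(O)=O
glucose,5793,OCC1OC(O)C(O)C(O)C1O
fructose,2723872,OCC(=O)C(O)C(O)C(O)CO
serotonin,5202,NCCC1=CNC2=CC=C(O)C=C12
tyramine,5610,NCCC1=CC=C(O)C=C1
histamine,774,NCCC1=CNC=N1
dopamine,681,NCCC1=CC=C(O)C(O)=C1
alanine,5950,CC(N)C(O)=O
glycine,750,NCC(O)=O
leucine,6106,CC(C)CC(N)C(O)=O
valine,6287,CC(C)C(N)C(O)=O
phenylalanine,6140,NC(CC1=CC=CC=C1)C(O)=O
tryptophan,6305,NC(CC1=CNC2=CC=CC=C12)C(O)=O
linoleic acid,5280450,CCCCCC=CCC=CCCCCCCCC(O)=O
oleic acid,445639,CCCCCCCCC=CCCCCCCCC(O)=O
palmitic acid,985,CCCCCCCCCCCCCCCC(O)=O
stearic acid,5281,CCCCCCCCCCCCCCCCCC(O)=O
nicotinic acid,938,OC(=O)C1=CC=CN=C1
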