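p53	Tumor Suppressor Protein p53
p63	Tumor Protein p63
Cyclin-D1	Cyclin D1
CK 7	Keratin-7
CK 20	Keratin-20
ErbB-2	Receptor, ErbB-2
WT-1	Genes, Wilms Tumor
Wilms tumor 1-protein	Genes, Wilms Tumor
EGFR	Receptor, Epidermal Growth Factor
FOXP3	Forkhead Box Protein P3
PDPN	Podoplanin
MLH-1	MutL Protein Homolog 1
ERCC1	Endonuclease ERCC1
CDH17	Cadherin 17
CD44	Antigens, CD44
CD10	Neprilysin
CD79 α	Antigens, CD79
GAL3	Galectin 3
DESMIN	Desmin
Factor VIII	Factor VIII
MIB-1	Ki-67 Antigen
Ki-67	Ki-67 Antigen
Vimentin	Vimentin
S-100	S100 Proteins
SMA	Actins, Smooth Muscle
CEA	Carcinoembryonic Antigen
Chromogranin A	Chromogranin A
Synaptophysin	Synaptophysin
TTF-1	Thyroid Nuclear Factor 1
ER	Receptors, Estrogen
PR	Receptors, Progesterone
Calretinin	Calbindin 2
CD3	Antigens, CD3
CD20	Antigens, CD20
Thymidylate synthase	Thymidylate Synthase
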