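Infiltrating duct carcinoma	Carcinoma, Ductal, Breast
Invasive ductal carcinoma	Carcinoma, Ductal, Breast
Adenocarcinoma	Adenocarcinoma
Gastric carcinoma	Carcinoma, Gastric
Tubular adenoma	Adenoma, Tubular
Squamous cell carcinoma	Carcinoma, Squamous Cell
Small cell carcinoma	Carcinoma, Small Cell
Hepatocellular carcinoma	Carcinoma, Hepatocellular
Renal cell carcinoma	Carcinoma, Renal Cell
Papillary thyroid carcinoma	Thyroid Cancer, Papillary
Urothelial carcinoma	Carcinoma, Transitional Cell
Melanoma	Melanoma
Diffuse large B-cell lymphoma	Lymphoma, Large B-Cell, Diffuse
Fibrocystic change	Fibrocystic Breast Disease
Chronic gastritis	Gastritis
Leiomyoma	Leiomyoma
Serous carcinoma	Cystadenocarcinoma, Serous
Mucinous adenocarcinoma	Adenocarcinoma, Mucinous
Glioblastoma	Glioblastoma
Meningioma	Meningioma
Signet ring cell carcinoma	Carcinoma, Signet Ring Cell
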