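Breast	Breast
Lung	Lung
Stomach	Stomach
Colon	Colon
Rectum	Rectum
Liver	Liver
Pancreas	Pancreas
Kidney	Kidney
Prostate	Prostate
Thyroid	Thyroid gland
Thyroid gland	Thyroid gland
Ovary	Ovary
Uterus	Uterus
Uterine cervix	Uterine cervix
Urinary bladder	Urinary bladder
Skin	Skin
Lymph node	Lymph node
Brain	Brain
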