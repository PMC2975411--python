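tissue	n_selected	n_integrated
Brain (various regions)	645	616
Pituitary gland	12	12
Thyroid gland	16	9
Adrenal gland	25	25
Pancreas	56	55
Skeletal muscle	122	109
Skin	101	101
Adipose tissue	80	80
Retina	12	12
Gingiva	71	71
Salivary gland	18	18
Tongue	22	20
Stomach	51	51
Small intestine	59	59
Colon	107	105
Liver	117	117
Kidney	73	73
Breast	132	132
Ovary	61	59
Uterus	117	117
Placenta	56	56
Umbilical cord	54	54
Testis	36	36
Prostate	58	58
Nasal epithelium	31	31
Airway epithelium	89	89
Lung	66	66
Alveolar macrophage	88	87
Heart	31	31
Tonsil	13	13
Lymph node	14	14
Blood (various cell types)	413	409
Other tissues	184	183
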