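# table: T5
# description: co-expression interaction counts per tissue
# printed_total: 189530
tissue	value
Adipose tissue	5
Adrenal gland	6
Bladder	199
Blood	96
Blood vessel	—
Brain	1512
Breast	2
Cervix uteri	5
Colon	6
Esophagus	—
Fallopian tube	189
Heart	33
Kidney	385
Liver	476
Lung	13
Muscle	81
Nerve	5
Ovary	1
Pancreas	3
Pituitary	137
Prostate	51
Salivary gland	86
Skin	711
Small intestine	1197
Spleen	136
Stomach	37
Testis	184041
Thyroid	6
Uterus	—
Vagina	107
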