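# table: T4
# description: tissue-specific mRNA counts per tissue
# printed_total: 3668
tissue	value
Adipose tissue	16
Adrenal gland	41
Bladder	28
Blood	101
Blood vessel	4
Brain	260
Breast	4
Cervix uteri	9
Colon	11
Esophagus	2
Fallopian tube	29
Heart	48
Kidney	87
Liver	237
Lung	34
Muscle	127
Nerve	27
Ovary	20
Pancreas	83
Pituitary	155
Prostate	33
Salivary gland	72
Skin	166
Small intestine	144
Spleen	219
Stomach	40
Testis	1563
Thyroid	35
Uterus	6
Vagina	67
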