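# table: T3
# description: tissue-specific lncRNA counts per tissue
# printed_total: 4687
tissue	value
Adipose tissue	16
Adrenal gland	42
Bladder	29
Blood	31
Blood vessel	23
Brain	172
Breast	8
Cervix uteri	14
Colon	10
Esophagus	1
Fallopian tube	39
Heart	46
Kidney	116
Liver	108
Lung	34
Muscle	35
Nerve	48
Ovary	32
Pancreas	52
Pituitary	159
Prostate	54
Salivary gland	56
Skin	44
Small intestine	61
Spleen	94
Stomach	14
Testis	3264
Thyroid	53
Uterus	11
Vagina	21
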