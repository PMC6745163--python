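# table: T1
# description: number of normal samples per tissue
# printed_total: 8553
tissue	value
Adipose tissue	577
Adrenal gland	145
Bladder	11
Blood	511
Blood vessel	689
Brain	1259
Breast	214
Cervix uteri	11
Colon	345
Esophagus	686
Fallopian tube	6
Heart	412
Kidney	32
Liver	119
Lung	320
Muscle	430
Nerve	304
Ovary	97
Pancreas	171
Pituitary	103
Prostate	106
Salivary gland	57
Skin	890
Small intestine	88
Spleen	104
Stomach	192
Testis	172
Thyroid	323
Uterus	83
Vagina	96
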