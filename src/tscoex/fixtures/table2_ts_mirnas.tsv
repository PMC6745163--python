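# table: T2
# description: tissue-specific miRNA identifiers per tissue
# printed_total: 95
tissue	value
Adipose tissue	—
Adrenal gland	miR-4263, miR-1224, miR-4709, miR-33b
Bladder	miR-3972, miR-5091, miR-93, miR-4469
Blood	miR-144, miR-3909, miR-223
Blood vessel	—
Brain	miR-3682, miR-4477b, miR-3665, miR-628
Breast	—
Cervix uteri	miR-320b2, miR-4269, miR-548i1, miR-593
Colon	—
Esophagus	—
Fallopian tube	miR-3671, miR-3125, miR-3622a, miR-23b, miR-3613, miR-369, miR-1225
Heart	—
Kidney	miR-1227
Liver	miR-1295a, miR-4783, miR-135a1, miR-1236, miR-4482-1, miR-4751
Lung	miR-4635, miR-4668
Muscle	miR-133bhg, miR-133b, miR-133a2
Nerve	miR-378h, miR-4500hg, miR-5093, miR-657
Ovary	miR-548I2, miR-3960, miR-433, miR-1257
Pancreas	—
Pituitary	miR-137hg, miR-339, miR-770, miR-1179, miR-212, miR-7-3hg, miR-7-3, miR-659
Prostate	miR-224
Salivary gland	miR-642a
Skin	miR-205hg, miR-567, miR-936, miR-203
Small intestine	miR-559, miR-3944, miR-192, miR-194-2, miR-147b
Spleen	miR-589, miR-378i, miR-1587
Stomach	—
Testis	miR-1302-11, miR-4258, miR-4436a, miR-1302-3, miR-663b, miR-219-1, miR-3943, miR-5707, miR-3150b, miR-1302-2, miR-let7dhg, miR-3689b, miR-202, miR-26a2, miR-5188, miR-4313, miR-3180-3, miR-632, miR-3615, miR-4526, miR-181c, miR-639, miR-519a2, miR-371b, miR-663a
Thyroid	miR-3907, miR-135a2
Uterus	—
Vagina	—
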