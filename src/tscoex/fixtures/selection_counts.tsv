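# per-biotype RNA tallies before and after the input pre-filters
biotype	initial	retained
miRNA	1368	240
lncRNA	10167	9297
mRNA	30441	19028
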