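cancer_type	n_neg	n_plus	n_plusplus
lung	8	34	50
colon	2	16	30
thyroid	2	16	31
liver	5	36	165
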