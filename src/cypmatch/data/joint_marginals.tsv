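# Published joint-assessment marginals per method pair and enzyme:
# n_joint = drugs assessed by both the manual method and the automatic
# method with the given resource; manual_substrates / automatic_substrates
# are each method's substrate counts within that joint set.
resource	enzyme	n_joint	manual_substrates	automatic_substrates
drugbank	CYP2D6	100	9	12
drugbank	CYP2C19	100	8	11
drugbank	CYP2C9	100	6	17
fda	CYP2D6	12	3	1
fda	CYP2C19	12	3	1
fda	CYP2C9	12	0	0
flockhart	CYP2D6	26	7	6
flockhart	CYP2C19	26	7	6
flockhart	CYP2C9	26	2	5
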