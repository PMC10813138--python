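# Published per-drug classification differences between the manual method
# and each automatic resource.  x = classified substrate, - = assessed but
# not classified substrate, NA = not assessed by that resource.
# entries = medication entries for the drug in the source dataset (N=23878).
# "(dex)ibuprofen" in the source is encoded as two drugs (ibuprofen,
# dexibuprofen) with the jointly printed entry count kept on ibuprofen.
enzyme	drug	manual	drugbank	fda	flockhart	entries
CYP2D6	simvastatin	x	x	-	-	628
CYP2D6	acetaminophen	-	x	NA	-	56
CYP2D6	escitalopram	x	x	-	-	31
CYP2D6	caffeine	-	x	-	-	11
CYP2D6	dapagliflozin	-	x	NA	NA	10
CYP2C19	simvastatin	-	x	-	-	628
CYP2C19	ibuprofen	-	x	NA	-	268
CYP2C19	dexibuprofen	-	x	NA	-	0
CYP2C19	clopidogrel	x	x	-	-	257
CYP2C19	apixaban	x	x	NA	-	218
CYP2C19	naloxone	-	x	NA	NA	137
CYP2C19	tilidine	x	-	NA	NA	110
CYP2C19	escitalopram	x	x	-	-	31
CYP2C9	acetylsalicylic acid	-	x	NA	NA	952
CYP2C9	valsartan	-	x	NA	NA	259
CYP2C9	clopidogrel	-	x	-	x	257
CYP2C9	apixaban	x	x	NA	-	218
CYP2C9	omeprazole	-	x	-	-	121
CYP2C9	carvedilol	-	x	NA	-	97
CYP2C9	ondansetron	-	x	NA	-	87
CYP2C9	losartan	-	x	NA	x	31
CYP2C9	irbesartan	-	x	NA	x	25
CYP2C9	olodaterol	-	x	NA	x	17
CYP2C9	caffeine	-	x	-	-	11
CYP2C9	dapagliflozin	-	x	NA	-	10
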