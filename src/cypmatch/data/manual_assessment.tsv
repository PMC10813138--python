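# Consensus manual substrate assessments (transcription fixture): flags for
# drugs whose manual verdicts are documented in the published comparisons,
# plus classic substrates any review would flag.  Columns reviewer_a,
# reviewer_b, consensus are provenance only.
name	CYP2D6	CYP2C9	CYP2C19	reviewer_a	reviewer_b	consensus
simvastatin	x	-	-	r1	r2	yes
escitalopram	x	-	x	r1	r2	yes
clopidogrel	-	-	x	r1	r2	yes
apixaban	-	x	x	r1	r2	yes
tilidine	-	-	x	r1	r2	yes
metoprolol	x	-	-	r1	r2	yes
amitriptyline	x	-	x	r1	r2	yes
tramadol	x	-	-	r1	r2	yes
omeprazole	-	-	x	r1	r2	yes
phenprocoumon	-	x	-	r1	r2	yes
ibuprofen	-	x	-	r1	r2	yes
pantoprazole	-	-	x	r1	r2	yes
ramipril	-	-	-	r1	r2	yes
acetylsalicylic acid	-	-	-	r1	r2	yes
metamizole	-	-	-	r1	r2	yes
torasemide	-	-	-	r1	r2	yes
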