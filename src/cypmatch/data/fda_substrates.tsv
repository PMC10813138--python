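#policy=LISTED_ONLY
#resource_id=fda
#version=transcribed-examples-2023
# Transcription fixture: FDA table of examples of clinical substrates,
# limited to drugs exercised by the documented analyses plus a few classic
# index substrates.  Deliberately does NOT list pantoprazole.
name	atc	CYP2D6	CYP2C9	CYP2C19	note
desipramine	N06AA01	1	0	0	sensitive index substrate
dextromethorphan	R05DA09	1	0	0	sensitive index substrate
nebivolol	C07AB12	1	0	0
atomoxetine	N06BA09	1	0	0
metoprolol	C07AB02	1	0	0
celecoxib	M01AH01	0	1	0
flurbiprofen	M01AE09	0	1	0
tolbutamide	A10BB03	0	1	0
warfarin	B01AA03	0	1	0
omeprazole	A02BC01	0	0	1
lansoprazole	A02BC03	0	0	1
mephenytoin	N03AB04	0	0	1
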