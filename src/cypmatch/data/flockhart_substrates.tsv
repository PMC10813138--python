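#policy=LISTED_ONLY
#resource_id=flockhart
#version=transcribed-examples-2023
# Transcription fixture: Flockhart-style interaction-table rows limited to
# drugs exercised by the documented analyses plus classic teaching examples.
# Losartan and irbesartan are listed as CYP2C9 substrates; other angiotensin
# receptor blockers (e.g. valsartan) are not listed.
name	atc	CYP2D6	CYP2C9	CYP2C19	note
metoprolol	C07AB02	1	0	0
amitriptyline	N06AA09	1	0	1
venlafaxine	N06AX16	1	0	0
tramadol	N02AX02	1	0	0
omeprazole	A02BC01	0	0	1
clopidogrel	B01AC04	0	1	1
losartan	C09CA01	0	1	0
irbesartan	C09CA04	0	1	0
olodaterol	R03AC19	0	1	0
phenytoin	N03AB02	0	1	0
escitalopram	N06AB10	1	0	1
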