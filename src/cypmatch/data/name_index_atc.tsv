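atc	name
C09AA05	ramipril
C03AA03	hydrochlorothiazide
C07AB02	metoprolol
C10AA01	simvastatin
N06AB10	escitalopram
B01AC04	clopidogrel
B01AF02	apixaban
N02AX01	tilidine
A02BC01	omeprazole
A02BC02	pantoprazole
M01AE01	ibuprofen
M01AE14	dexibuprofen
C09CA01	losartan
C09CA04	irbesartan
C09CA03	valsartan
R03AC19	olodaterol
B01AC06	acetylsalicylic acid
N02BB02	metamizole
C03CA04	torasemide
C08CA01	amlodipine
H03AA01	levothyroxine
N06BC01	caffeine
N02BE01	acetaminophen
V03AB15	naloxone
C07AG02	carvedilol
A04AA01	ondansetron
A10BK01	dapagliflozin
B01AA04	phenprocoumon
N06AA09	amitriptyline
N02AX02	tramadol
M04AA01	allopurinol
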