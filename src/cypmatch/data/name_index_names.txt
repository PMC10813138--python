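ramipril
hydrochlorothiazide
metoprolol
simvastatin
escitalopram
clopidogrel
apixaban
tilidine
omeprazole
pantoprazole
ibuprofen
dexibuprofen
losartan
irbesartan
valsartan
olodaterol
acetylsalicylic acid
metamizole
torasemide
amlodipine
levothyroxine
caffeine
acetaminophen
naloxone
carvedilol
ondansetron
dapagliflozin
phenprocoumon
amitriptyline
tramadol
allopurinol
desipramine
dextromethorphan
nebivolol
atomoxetine
celecoxib
flurbiprofen
tolbutamide
warfarin
lansoprazole
mephenytoin
venlafaxine
phenytoin
cholecalciferol
potassium
magnesium
formoterol
tiotropium bromide
salbutamol
levodopa
ipratropium bromide
oxycodone
budesonide
lorazepam
nitrendipine
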