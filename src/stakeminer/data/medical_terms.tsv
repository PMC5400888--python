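# Medical term lexicon: term <TAB> category <TAB> UMLS-style semantic type.
# Semantic types: sosy=sign/symptom, dsyn=disease/syndrome, patf=pathologic function,
# diap=diagnostic procedure, lbpr=laboratory procedure, topp=therapeutic procedure,
# phsu=pharmacologic substance.
cough	medical	sosy
pain	medical	sosy
breathless	medical	sosy
symptoms	medical	sosy
chest pain	medical	sosy
painful	medical	sosy
shortness of breath	medical	sosy
wheezing	medical	sosy
short of breath	medical	sosy
coughing up blood	medical	sosy
nausea	medical	sosy
tired	medical	sosy
thirsty	medical	sosy
fatigue	medical	sosy
frequent urination	medical	sosy
hungry	medical	sosy
dizzy	medical	sosy
itchy	medical	sosy
sore	medical	sosy
tingling	medical	sosy
breast pain	medical	sosy
nipple discharge	medical	sosy
itching	medical	sosy
hot flashes	medical	sosy
infection	medical	patf
bronchitis	medical	dsyn
pneumonia	medical	dsyn
tuberculosis	medical	dsyn
asthma	medical	dsyn
pleural effusion	medical	dsyn
copd	medical	dsyn
emphysema	medical	dsyn
collapsed lung	medical	patf
atelectasis	medical	patf
hypoglycemia	medical	dsyn
low blood sugar	medical	patf
dka	medical	dsyn
obesity	medical	dsyn
pcos	medical	dsyn
kidney disease	medical	dsyn
coma	medical	dsyn
diabetic neuropathy	medical	dsyn
bgs	medical	patf
rash	medical	dsyn
lymph edema	medical	dsyn
fibrocystic breast	medical	dsyn
mastitis	medical	dsyn
idc	medical	dsyn
eczema	medical	dsyn
complex cyst	medical	dsyn
complex cysts	medical	dsyn
neuropathy	medical	dsyn
fibrocystic breast disease	medical	dsyn
fibrocystic disease	medical	dsyn
scans	medical	diap
x-ray	medical	diap
cat scan	medical	diap
mri	medical	diap
biopsy	medical	diap
pet scan	medical	diap
chest x-ray	medical	diap
imaging	medical	diap
biopsy needle	medical	diap
bronchoscopy	medical	diap
ultrasound	medical	diap
mammogram	medical	diap
screening	medical	diap
bi-rads	medical	diap
core biopsy	medical	diap
blood test	medical	lbpr
glucose test	medical	lbpr
fasting test	medical	lbpr
fasting blood sugar	medical	lbpr
hemoglobin a1c test	medical	lbpr
gtts	medical	lbpr
glucose tolerance test	medical	lbpr
chemo	medical	topp
operation	medical	topp
surgery	medical	topp
radiation	medical	topp
therapy	medical	topp
chemotherapy	medical	topp
removal	medical	topp
radiation therapy	medical	topp
wedge resection	medical	topp
lobectomy	medical	topp
infusion	medical	topp
injection	medical	topp
transplant	medical	topp
dialysis	medical	topp
rx	medical	topp
ect	medical	topp
insulin injection	medical	topp
cde	medical	topp
amputation	medical	topp
radiotherapy	medical	topp
mastectomy	medical	topp
lumpectomy	medical	topp
implant	medical	topp
surgical	medical	topp
silicas	medical	phsu
morphine	medical	phsu
advil	medical	phsu
tarceva	medical	phsu
chantix	medical	phsu
carboplatin	medical	phsu
alimta	medical	phsu
dilaudid	medical	phsu
taxol	medical	phsu
coumadin	medical	phsu
insulin	medical	phsu
lantus	medical	phsu
januvia	medical	phsu
metformin	medical	phsu
glucophage	medical	phsu
actos	medical	phsu
avandia	medical	phsu
amaryl	medical	phsu
marijuana	medical	phsu
glipizide	medical	phsu
tamoxifen	medical	phsu
arimidex	medical	phsu
femara	medical	phsu
taxotere	medical	phsu
effexor	medical	phsu
docetaxel	medical	phsu
valium	medical	phsu
raloxifene	medical	phsu
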