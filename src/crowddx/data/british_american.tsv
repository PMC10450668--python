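# Token-level British -> US spelling map (tab-separated). Exact lowercase
# token lookup; plurals are handled by singularizing first and re-applying.
anaemia	anemia
anaemic	anemic
oedema	edema
oedematous	edematous
oesophagus	esophagus
oesophageal	esophageal
oesophagitis	esophagitis
haemorrhage	hemorrhage
haemorrhagic	hemorrhagic
haemorrhoid	hemorrhoid
haematoma	hematoma
haematuria	hematuria
haemoglobin	hemoglobin
haemolytic	hemolytic
haemophilia	hemophilia
haemoptysis	hemoptysis
diarrhoea	diarrhea
dyspnoea	dyspnea
apnoea	apnea
coeliac	celiac
leukaemia	leukemia
anaesthesia	anesthesia
anaesthetic	anesthetic
paediatric	pediatric
orthopaedic	orthopedic
gynaecology	gynecology
gynaecological	gynecological
foetal	fetal
foetus	fetus
goitre	goiter
fibre	fiber
litre	liter
colour	color
tumour	tumor
labour	labor
oestrogen	estrogen
ischaemia	ischemia
ischaemic	ischemic
caecum	cecum
caecal	cecal
faeces	feces
faecal	fecal
septicaemia	septicemia
toxaemia	toxemia
uraemia	uremia
uraemic	uremic
hypoglycaemia	hypoglycemia
hyperglycaemia	hyperglycemia
hypercalcaemia	hypercalcemia
hypocalcaemia	hypocalcemia
hyperkalaemia	hyperkalemia
hypokalaemia	hypokalemia
hypernatraemia	hypernatremia
hyponatraemia	hyponatremia
bacteraemia	bacteremia
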