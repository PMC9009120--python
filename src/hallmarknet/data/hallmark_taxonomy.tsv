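term_id	label	level	parent_id	root_hallmark	synonyms
GI	genomic instability	1		GI	genomic instability|genome instability|genomic instabilities
GI.1	DNA damage	2	GI	GI	dna damage|dna lesions|dna damage accumulation
GI.2	somatic mutation	2	GI	GI	somatic mutation|somatic mutations|somatic mutation burden
GI.3	chromosomal instability	2	GI	GI	chromosomal instability|chromosome instability|aneuploidy
GI.1.1	DNA double-strand break	3	GI.1	GI	double-strand break|double strand breaks|dna double-strand breaks
GI.1.2	DNA repair deficiency	3	GI.1	GI	dna repair deficiency|defective dna repair|impaired dna repair
GI.2.1	clonal hematopoiesis	3	GI.2	GI	clonal hematopoiesis|clonal haematopoiesis
GI.1.2.1	nucleotide excision repair defect	4	GI.1.2	GI	nucleotide excision repair defect|ner deficiency
TA	telomere attrition	1		TA	telomere attrition|telomere shortening|telomere erosion|shortened telomeres
TA.1	telomere dysfunction	2	TA	TA	telomere dysfunction|dysfunctional telomeres
TA.2	telomerase deficiency	2	TA	TA	telomerase deficiency|telomerase dysfunction
TA.3	telomere damage	2	TA	TA	telomere damage|telomeric dna damage
TA.1.1	telomere uncapping	3	TA.1	TA	telomere uncapping|uncapped telomeres
TA.2.1	telomerase mutation	3	TA.2	TA	tert mutation|terc mutation|telomerase mutation
TA.1.1.1	shelterin loss	4	TA.1.1	TA	shelterin loss|shelterin dysfunction
EA	epigenetic alterations	1		EA	epigenetic alteration|epigenetic alterations|epigenetic changes|epigenetic dysregulation
EA.1	DNA methylation change	2	EA	EA	dna methylation change|dna hypermethylation|dna hypomethylation
EA.2	histone modification	2	EA	EA	histone modification|histone acetylation|histone methylation
EA.3	chromatin remodeling	2	EA	EA	chromatin remodeling|chromatin remodelling|chromatin reorganization
EA.1.1	epigenetic clock drift	3	EA.1	EA	epigenetic clock|epigenetic age acceleration
EA.2.1	sirtuin dysregulation	3	EA.2	EA	sirtuin dysregulation|sirt1 decline|sirt6 decline
EA.3.1	heterochromatin loss	3	EA.3	EA	heterochromatin loss|loss of heterochromatin
LOP	loss of proteostasis	1		LOP	loss of proteostasis|proteostasis loss|impaired proteostasis|proteostasis collapse
LOP.1	protein misfolding	2	LOP	LOP	protein misfolding|misfolded protein|misfolded proteins
LOP.2	protein aggregation	2	LOP	LOP	protein aggregation|protein aggregates|amyloid aggregation
LOP.3	impaired autophagy	2	LOP	LOP	impaired autophagy|autophagy impairment|defective autophagy
LOP.4	chaperone decline	2	LOP	LOP	chaperone decline|heat shock response decline|hsp70 decline
LOP.2.1	amyloid-beta accumulation	3	LOP.2	LOP	amyloid-beta|amyloid beta|amyloid-beta accumulation
LOP.2.2	alpha-synuclein aggregation	3	LOP.2	LOP	alpha-synuclein|α-synuclein|synuclein aggregates
LOP.3.1	proteasome dysfunction	3	LOP.3	LOP	proteasome dysfunction|ubiquitin-proteasome system decline
DNS	deregulated nutrient sensing	1		DNS	deregulated nutrient sensing|dysregulated nutrient sensing|nutrient sensing dysregulation
DNS.1	insulin resistance	2	DNS	DNS	insulin resistance|insulin insensitivity
DNS.2	mTOR hyperactivation	2	DNS	DNS	mtor hyperactivation|mtor activation|mtor signaling
DNS.3	IGF-1 signaling change	2	DNS	DNS	igf-1 signaling|igf1 signaling|insulin-igf-1 signalling
DNS.4	AMPK dysregulation	2	DNS	DNS	ampk dysregulation|ampk signaling decline
DNS.2.1	S6 kinase overactivity	3	DNS.2	DNS	s6 kinase|s6k1 overactivity
DNS.3.1	growth hormone axis change	3	DNS.3	DNS	growth hormone axis|gh-igf-1 axis
MD	mitochondrial dysfunction	1		MD	mitochondrial dysfunction|mitochondrial decline|impaired mitochondria
MD.1	oxidative stress	2	MD	MD	oxidative stress|reactive oxygen species|ros accumulation
MD.2	mtDNA mutation	2	MD	MD	mtdna mutation|mitochondrial dna mutation|mtdna damage
MD.3	impaired mitophagy	2	MD	MD	impaired mitophagy|mitophagy impairment|defective mitophagy
MD.4	electron transport chain defect	2	MD	MD	electron transport chain defect|respiratory chain deficiency
MD.1.1	mitochondrial ROS	3	MD.1	MD	mitochondrial ros|mitochondrial superoxide
MD.4.1	complex I deficiency	3	MD.4	MD	complex i deficiency|complex 1 deficiency
CS	cellular senescence	1		CS	cellular senescence|cell senescence|senescent cells|senescent cell
CS.1	SASP	2	CS	CS	senescence-associated secretory phenotype|sasp
CS.2	senescence arrest	2	CS	CS	replicative senescence|senescence-associated growth arrest
CS.3	immunosenescence	2	CS	CS	immunosenescence|immune senescence
CS.1.1	SASP cytokine secretion	3	CS.1	CS	sasp cytokines|senescence-associated cytokines
CS.2.1	p16 activation	3	CS.2	CS	p16ink4a activation|p16 activation|cdkn2a induction
CS.2.2	p53-p21 axis	3	CS.2	CS	p21 induction|p53-p21 axis
SCE	stem cell exhaustion	1		SCE	stem cell exhaustion|stem cell depletion|stem cell decline|exhausted stem cells
SCE.1	hematopoietic stem cell decline	2	SCE	SCE	hematopoietic stem cell decline|hsc exhaustion|hsc aging
SCE.2	satellite cell loss	2	SCE	SCE	satellite cell loss|muscle stem cell decline
SCE.3	neural stem cell decline	2	SCE	SCE	neural stem cell decline|neurogenesis decline
SCE.4	intestinal stem cell decline	2	SCE	SCE	intestinal stem cell decline|isc decline
SCE.1.1	myeloid bias	3	SCE.1	SCE	myeloid bias|myeloid skewing
SCE.2.1	regenerative capacity loss	3	SCE.2	SCE	impaired regeneration|regenerative decline
AIC	altered intercellular communication	1		AIC	altered intercellular communication|intercellular communication decline|impaired intercellular communication
AIC.1	inflammaging	2	AIC	AIC	inflammaging|inflamm-aging|chronic low-grade inflammation
AIC.2	endocrine dysregulation	2	AIC	AIC	endocrine dysregulation|hormonal dysregulation
AIC.3	neuroendocrine change	2	AIC	AIC	neuroendocrine dysfunction|neurohormonal dysregulation
AIC.1.1	NF-kB activation	3	AIC.1	AIC	nf-kb activation|nf-κb activation|nfkb signaling
AIC.1.2	TNF-alpha elevation	3	AIC.1	AIC	tnf-alpha elevation|tnf-α elevation|tumor necrosis factor alpha
AIC.1.1.1	IL-6 elevation	4	AIC.1.1	AIC	il-6 elevation|interleukin-6 elevation
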