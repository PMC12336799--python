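# Curated subset of the AAPM TG-263 organ-at-risk nomenclature
# with English / German / Dutch synonym columns (lang:term, pipe-separated).
# version=tg263harm-subset-1
standard_name	concept_id	category	laterality	spatial_qualifier	plurality	synonyms
SpinalCord	spinal_cord	organ	none		singular	en:spinal cord|de:rueckenmark|de:myelum|nl:ruggenmerg|nl:myelum
SpinalCord_Cerv	spinal_cord	substructure	none	Cerv	singular	en:cervical spinal cord|de:halsmark
SpinalCanal	spinal_canal	organ	none		singular	en:spinal canal|de:spinalkanal|nl:wervelkanaal
Brain	brain	organ	none		singular	en:brain|de:gehirn|de:hirn|nl:hersenen
Brainstem	brainstem	organ	none		singular	en:brainstem|en:brain stem|de:hirnstamm|nl:hersenstam
Cerebellum	cerebellum	organ	none		singular	en:cerebellum|de:kleinhirn|nl:kleine hersenen
Hippocampus_L	hippocampus	substructure	left		singular	en:hippocampus
Hippocampus_R	hippocampus	substructure	right		singular	
Lobe_Temporal_L	temporal_lobe	substructure	left		singular	en:temporal lobe|de:schlaefenlappen|nl:temporaalkwab
Lobe_Temporal_R	temporal_lobe	substructure	right		singular	
OpticChiasm	optic_chiasm	organ	none		singular	en:optic chiasm|en:chiasm|de:chiasma opticum|nl:chiasma
OpticNrv_L	optic_nerve	organ	left		singular	en:optic nerve|de:sehnerv|nl:oogzenuw|nl:nervus opticus
OpticNrv_R	optic_nerve	organ	right		singular	
Pituitary	pituitary	organ	none		singular	en:pituitary|en:pituitary gland|de:hypophyse|nl:hypofyse
Eye_L	eye	organ	left		singular	en:eye|en:globe|de:auge|nl:oog
Eye_R	eye	organ	right		singular	
Eyes	eye	composite	bilateral		plural	en:eyes|de:augen|nl:ogen
Lens_L	lens	substructure	left		singular	en:lens|en:eye lens|de:augenlinse|de:linse|nl:ooglens
Lens_R	lens	substructure	right		singular	
Retina_L	retina	substructure	left		singular	en:retina|de:netzhaut|nl:netvlies
Retina_R	retina	substructure	right		singular	
Cornea_L	cornea	substructure	left		singular	en:cornea|de:hornhaut|nl:hoornvlies
Cornea_R	cornea	substructure	right		singular	
Glnd_Lacrimal_L	lacrimal_gland	organ	left		singular	en:lacrimal gland|de:traenendruese|nl:traanklier
Glnd_Lacrimal_R	lacrimal_gland	organ	right		singular	
Cochlea_L	cochlea	organ	left		singular	en:cochlea|de:hoerschnecke|nl:slakkenhuis
Cochlea_R	cochlea	organ	right		singular	
Ear_Internal_L	inner_ear	organ	left		singular	en:inner ear|de:innenohr|nl:binnenoor
Ear_Internal_R	inner_ear	organ	right		singular	
Parotid_L	parotid_gland	organ	left		singular	en:parotid|en:parotid gland|de:ohrspeicheldruese|nl:parotis
Parotid_R	parotid_gland	organ	right		singular	
Parotids	parotid_gland	composite	bilateral		plural	en:parotids|nl:parotiden
Glnd_Submand_L	submandibular_gland	organ	left		singular	en:submandibular gland|de:unterkieferdruese|nl:submandibularis
Glnd_Submand_R	submandibular_gland	organ	right		singular	
Glnd_Thyroid	thyroid	organ	none		singular	en:thyroid|en:thyroid gland|de:schilddruese|nl:schildklier
Thymus	thymus	organ	none		singular	en:thymus|de:thymusdruese|nl:zwezerik
Bone_Mandible	mandible	organ	none		singular	en:mandible|en:lower jaw|de:unterkiefer|nl:onderkaak
Bone_Hyoid	hyoid	organ	none		singular	en:hyoid bone|de:zungenbein|nl:tongbeen
Cavity_Oral	oral_cavity	organ	none		singular	en:oral cavity|de:mundhoehle|nl:mondholte
Lips	lips	organ	none		plural	en:lips|de:lippen|nl:lippen
Larynx	larynx	organ	none		singular	en:larynx|en:voice box|de:kehlkopf|nl:strottenhoofd
Glottis	glottis	substructure	none		singular	en:glottis|de:stimmritze
Pharynx	pharynx	organ	none		singular	en:pharynx|de:rachen|nl:keelholte
Musc_Constrict	pharyngeal_constrictor	substructure	none		singular	en:pharyngeal constrictor|en:constrictor muscles|de:schluckmuskeln|nl:farynxconstrictor
Musc_Masseter_L	masseter	substructure	left		singular	en:masseter|en:masseter muscle|de:kaumuskel
Musc_Masseter_R	masseter	substructure	right		singular	
Musc_Sclmast_L	sternocleidomastoid	substructure	left		singular	en:sternocleidomastoid|de:kopfwender
Musc_Sclmast_R	sternocleidomastoid	substructure	right		singular	
BrachialPlex_L	brachial_plexus	organ	left		singular	en:brachial plexus|de:plexus brachialis|nl:plexus brachialis
BrachialPlex_R	brachial_plexus	organ	right		singular	
A_Carotid_L	carotid_artery	organ	left		singular	en:carotid artery|de:halsschlagader|nl:halsslagader
A_Carotid_R	carotid_artery	organ	right		singular	
Esophagus	esophagus	organ	none		singular	en:esophagus|en:oesophagus|de:speiseroehre|nl:slokdarm
Trachea	trachea	organ	none		singular	en:trachea|en:windpipe|de:luftroehre|nl:luchtpijp
Bronchus	bronchus	organ	none		singular	en:bronchus|en:main bronchus|de:hauptbronchus
Lung_L	lung	organ	left		singular	en:lung|de:lunge|nl:long
Lung_R	lung	organ	right		singular	
Lungs	lung	composite	bilateral		plural	en:lungs|de:lungen|nl:longen
Heart	heart	organ	none		singular	en:heart|de:herz|nl:hart
A_Aorta	aorta	organ	none		singular	en:aorta|de:hauptschlagader
V_Venacava	vena_cava	organ	none		singular	en:vena cava
GreatVes	great_vessels	composite	none		plural	en:great vessels|de:grosse gefaesse|nl:grote vaten
Breast_L	breast	organ	left		singular	en:breast|de:brust|nl:borst
Breast_R	breast	organ	right		singular	
Breasts	breast	composite	bilateral		plural	en:breasts|de:brueste|nl:borsten
Chestwall_L	chest_wall	organ	left		singular	en:chest wall|de:brustwand|nl:borstwand
Chestwall_R	chest_wall	organ	right		singular	
Liver	liver	organ	none		singular	en:liver|de:leber|nl:lever
Spleen	spleen	organ	none		singular	en:spleen|de:milz|nl:milt
Stomach	stomach	organ	none		singular	en:stomach|de:magen|nl:maag
Pancreas	pancreas	organ	none		singular	en:pancreas|de:bauchspeicheldruese|nl:alvleesklier
Gallbladder	gallbladder	organ	none		singular	en:gallbladder|de:gallenblase|nl:galblaas
Duodenum	duodenum	organ	none		singular	en:duodenum|de:zwoelffingerdarm|nl:twaalfvingerige darm
Bowel	bowel	organ	none		singular	en:bowel|de:darm|nl:darm
Bowel_Small	small_bowel	organ	none		singular	en:small bowel|en:small intestine|de:duenndarm|nl:dunne darm
Bowel_Large	large_bowel	organ	none		singular	en:large bowel|en:colon|de:dickdarm|nl:dikke darm
Colon_Sigmoid	sigmoid_colon	substructure	none		singular	en:sigmoid colon|de:sigma|nl:sigmoid
Kidney	kidney	organ	none		singular	en:kidney|de:niere|nl:nier
Kidney_L	kidney	organ	left		singular	
Kidney_R	kidney	organ	right		singular	
Kidneys	kidney	composite	bilateral		plural	en:kidneys|de:nieren|nl:nieren
Glnd_Adrenal_L	adrenal_gland	organ	left		singular	en:adrenal gland|de:nebenniere|nl:bijnier
Glnd_Adrenal_R	adrenal_gland	organ	right		singular	
Bladder	bladder	organ	none		singular	en:bladder|en:urinary bladder|de:harnblase|de:blase|nl:blaas
Rectum	rectum	organ	none		singular	en:rectum|de:enddarm|de:mastdarm|nl:endeldarm
Sphincter_Anal	anal_sphincter	organ	none		singular	en:anal sphincter|de:analsphinkter|de:schliessmuskel|nl:anale sfincter|nl:sfincter ani
Prostate	prostate	organ	none		singular	en:prostate|de:prostata|nl:prostaat
SeminalVes	seminal_vesicles	organ	none		plural	en:seminal vesicles|de:samenblasen|nl:zaadblaasjes
PenileBulb	penile_bulb	substructure	none		singular	en:penile bulb|de:penisbulbus|nl:bulbus penis
Testis_L	testis	organ	left		singular	en:testis|en:testicle|de:hoden|nl:teelbal
Testis_R	testis	organ	right		singular	
Uterus	uterus	organ	none		singular	en:uterus|en:womb|de:gebaermutter|nl:baarmoeder
Ovary_L	ovary	organ	left		singular	en:ovary|de:eierstock|nl:eierstok
Ovary_R	ovary	organ	right		singular	
Vagina	vagina	organ	none		singular	en:vagina|de:scheide
Urethra	urethra	organ	none		singular	en:urethra|de:harnroehre|nl:plasbuis
Femur_Head_L	femoral_head	substructure	left		singular	en:femoral head|de:femurkopf|de:hueftkopf|nl:femurkop|nl:heupkop
Femur_Head_R	femoral_head	substructure	right		singular	
CaudaEquina	cauda_equina	organ	none		singular	en:cauda equina|nl:cauda
Skin	skin	organ	none		singular	en:skin|de:haut|nl:huid
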