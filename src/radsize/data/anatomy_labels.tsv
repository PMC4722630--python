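# concept id	label
anatomical-entity	anatomical entity
anatomical-structure	anatomical structure
body-region	body region
thorax	thorax
abdomen	abdomen
mediastinum	mediastinum
neck	neck
axilla	axilla
pelvis	pelvis
RID13296	lymph node
RID7710	submental lymph node
mediastinal-lymph-node	mediastinal lymph node
axillary-lymph-node	axillary lymph node
aortopulmonary-lymph-node	aortopulmonary lymph node
cervical-lymph-node	cervical lymph node
inguinal-lymph-node	inguinal lymph node
pretracheal-lymph-node	pretracheal lymph node
RID86	spleen
liver	liver
RID205	kidney
left-kidney	left kidney
right-kidney	right kidney
gallbladder	gallbladder
RID33779	wall of gallbladder
RID229	ureter
aorta	aorta
RID580	ascending aorta
aortic-arch	aortic arch
rib	rib
lung	lung
trachea	trachea
pleura	pleura
portion-of-soft-tissue	portion of soft tissue
lesion	lesion
mass	mass
cyst	cyst
liver-lesion	liver lesion
lung-lesion	lung lesion
hepatic-cyst	hepatic cyst
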