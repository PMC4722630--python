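# child	parent	relation
anatomical-structure	anatomical-entity	subclass_of
body-region	anatomical-entity	subclass_of
thorax	body-region	subclass_of
abdomen	body-region	subclass_of
mediastinum	body-region	subclass_of
neck	body-region	subclass_of
axilla	body-region	subclass_of
pelvis	body-region	subclass_of
mediastinum	thorax	part_of
axilla	thorax	part_of
RID13296	anatomical-structure	subclass_of
RID7710	RID13296	subclass_of
mediastinal-lymph-node	RID13296	subclass_of
axillary-lymph-node	RID13296	subclass_of
aortopulmonary-lymph-node	RID13296	subclass_of
cervical-lymph-node	RID13296	subclass_of
inguinal-lymph-node	RID13296	subclass_of
pretracheal-lymph-node	RID13296	subclass_of
RID7710	neck	part_of
cervical-lymph-node	neck	part_of
mediastinal-lymph-node	mediastinum	part_of
aortopulmonary-lymph-node	mediastinum	part_of
pretracheal-lymph-node	mediastinum	part_of
axillary-lymph-node	axilla	part_of
inguinal-lymph-node	pelvis	part_of
RID86	anatomical-structure	subclass_of
RID86	abdomen	part_of
liver	anatomical-structure	subclass_of
liver	abdomen	part_of
RID205	anatomical-structure	subclass_of
RID205	abdomen	part_of
left-kidney	RID205	subclass_of
right-kidney	RID205	subclass_of
gallbladder	anatomical-structure	subclass_of
gallbladder	abdomen	part_of
RID33779	anatomical-structure	subclass_of
RID33779	gallbladder	part_of
RID229	anatomical-structure	subclass_of
RID229	abdomen	part_of
aorta	anatomical-structure	subclass_of
RID580	aorta	subclass_of
RID580	thorax	part_of
aortic-arch	aorta	subclass_of
aortic-arch	thorax	part_of
rib	anatomical-structure	subclass_of
rib	thorax	part_of
lung	anatomical-structure	subclass_of
lung	thorax	part_of
trachea	anatomical-structure	subclass_of
trachea	mediastinum	part_of
pleura	anatomical-structure	subclass_of
pleura	thorax	part_of
portion-of-soft-tissue	anatomical-structure	subclass_of
lesion	anatomical-structure	subclass_of
mass	lesion	subclass_of
cyst	lesion	subclass_of
liver-lesion	lesion	subclass_of
liver-lesion	liver	part_of
lung-lesion	lesion	subclass_of
lung-lesion	lung	part_of
hepatic-cyst	cyst	subclass_of
hepatic-cyst	liver	part_of
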