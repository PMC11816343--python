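symbol	protein_name	clinically_achievable	angiogenesis	inhibition_confirmed	kd_nM	ic50_nM
ABL1	Tyrosine-protein kinase ABL1	true	true	confirmed
BRAF	Serine/threonine-protein kinase B-raf	true	true	confirmed
CDK19	Cyclin-dependent kinase 19	false	false	unknown
CDK8	Cyclin-dependent kinase 8	false	false	unknown
CDKL2	Cyclin-dependent kinase-like 2	false	false	unknown
CSF1R	Macrophage colony-stimulating factor 1 receptor	false	false	unknown
DDR1	Epithelial discoidin domain-containing receptor 1	false	false	unknown
DDR2	Discoidin domain-containing receptor 2	true	false	confirmed
EPHA2	Ephrin type-A receptor 2	true	true	confirmed
EPHA6	Ephrin type-A receptor 6	false	false	unknown
EPHA8	Ephrin type-A receptor 8	false	false	unknown
FGFR1	Fibroblast growth factor receptor 1	true	true	confirmed		202
FGFR2	Fibroblast growth factor receptor 2	true	true	not_confirmed
FGFR3	Fibroblast growth factor receptor 3	false	false	not_confirmed
FGFR4	Fibroblast growth factor receptor 4	false	false	not_confirmed
FLT1	Vascular endothelial growth factor receptor 1	true	true	confirmed
FLT3	Receptor-type tyrosine-protein kinase FLT3	false	true	unknown
FLT4	Vascular endothelial growth factor receptor 3	true	true	confirmed
FRK	Tyrosine-protein kinase FRK	true	false	confirmed
HIPK4	Homeodomain-interacting protein kinase 4	false	false	unknown
KDR	Vascular endothelial growth factor receptor 2	true	true	confirmed
KIT	Mast/stem cell growth factor receptor Kit	true	true	confirmed
MAP2K5	Dual-specificity mitogen-activated protein kinase kinase 5	false	true	unknown
MAP3K19	Mitogen-activated protein kinase kinase kinase 19	false	false	unknown
MAP3K20	Mitogen-activated protein kinase kinase kinase 20	false	false	unknown
MAP3K7	Mitogen-activated protein kinase kinase kinase 7	false	false	unknown
MAP4K4	Mitogen-activated protein kinase kinase kinase kinase 4	false	false	unknown
MAPK11	Mitogen-activated protein kinase 11	true	true	confirmed
MAPK14	Mitogen-activated protein kinase 14	false	true	unknown
MAPK15	Mitogen-activated protein kinase 15	false	false	unknown
MAPK9	Mitogen-activated protein kinase 9	false	true	unknown
MKNK2	MAP kinase-interacting serine/threonine-protein kinase 2	false	false	unknown
MUSK	Muscle, skeletal receptor tyrosine-protein kinase	false	false	unknown
NTRK1	High-affinity nerve growth factor receptor	true	false	not_confirmed
NTRK3	NT-3 growth factor receptor	false	false	unknown
PDGFRA	Platelet-derived growth factor receptor alpha	true	true	confirmed
PDGFRB	Platelet-derived growth factor receptor beta	true	true	confirmed
RAF1	RAF proto-oncogene serine/threonine-protein kinase	true	true	confirmed
RET	Proto-oncogene tyrosine-protein kinase receptor Ret	true	false	confirmed
SLK	STE20-like serine/threonine-protein kinase	false	false	unknown
STK10	Serine/threonine-protein kinase 10	false	false	unknown
TAOK3	Serine/threonine-protein kinase TAO3	false	false	unknown
TEK	Angiopoietin-1 receptor	true	true	confirmed		311
TIE1	Tyrosine-protein kinase receptor Tie-1	false	true	unknown
TNIK	TRAF2 and NCK interacting kinase	false	false	unknown
TNNI3K	Serine/threonine-protein kinase TNNI3K	false	false	unknown
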