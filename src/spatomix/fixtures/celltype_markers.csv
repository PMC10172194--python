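cell_type,marker_gene_ids
Epithelial cell,EPCAM;KRT18;KRT8;MUC5AC;TFF1
Tumor epithelial cell,CEACAM5;MKI67;CLDN4;KRT17;MUC1
T cell,CD3D;CD3E;CD2;IL7R;TRBC2
B cell,CD79A;CD79B;MS4A1;IGHM;CD19
Fibroblast,COL1A1;COL1A2;DCN;LUM;PDGFRA
Smooth muscle cell,ACTA2;MYH11;DES;CNN1;TAGLN
Endothelial cell,PECAM1;VWF;CDH5;CLDN5;ENG
Erythrocyte,HBB;HBA1;HBA2;ALAS2;SLC4A1
Plasma cell,IGHG1;JCHAIN;MZB1;XBP1;CD38
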