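pathway_id,pathway_name,gene_ids,metabolite_ids
arg_pro_metabolism,Arginine and proline metabolism,GLS;GLUL;ASS1;ALDH18A1;PYCR1;OAT;ODC1;SRM;SMS;AGMAT,glutamine;glutamate;arginine;proline;ornithine;putrescine;spermidine;spermine
fa_de_novo_synthesis,Fatty acid de novo synthesis,ACACA;FASN;SCD;FADS2;ELOVL1,palmitic acid;stearic acid;oleic acid;linoleic acid;arachidonic acid
glycerophospholipid_metabolism,Glycerophospholipid metabolism,CHKA;ETNK1;PLD1;LYPLA2;CPT1A;CRAT,PC(34:1);PC(36:2);PE(34:1);PE(36:2)
glycolysis,Glycolysis and gluconeogenesis,HK2;GPI;PFKL;ALDOA;PKM;LDHA,glucose;lactic acid
tca_cycle,Citrate cycle,CS;ACO2;IDH1;SDHA;FH;MDH2,citric acid;succinic acid;malic acid;fumaric acid
purine_metabolism,Purine metabolism,HPRT1;PNP;ADA;XDH,hypoxanthine;inosine;adenine
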