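name,formula,monoisotopic_mass,compound_class
glutamine,C5H10N2O3,146.06914,amino acid
glutamate,C5H9NO4,147.05316,amino acid
arginine,C6H14N4O2,174.11168,amino acid
proline,C5H9NO2,115.06333,amino acid
ornithine,C5H12N2O2,132.08988,amino acid
alanine,C3H7NO2,89.04768,amino acid
serine,C3H7NO3,105.04259,amino acid
leucine,C6H13NO2,131.09463,amino acid
lysine,C6H14N2O2,146.10553,amino acid
phenylalanine,C9H11NO2,165.07898,amino acid
tryptophan,C11H12N2O2,204.08988,amino acid
tyrosine,C9H11NO3,181.07389,amino acid
valine,C5H11NO2,117.07898,amino acid
threonine,C4H9NO3,119.05824,amino acid
methionine,C5H11NO2S,149.05105,amino acid
putrescine,C4H12N2,88.10005,polyamine
spermidine,C7H19N3,145.15790,polyamine
spermine,C10H26N4,202.21575,polyamine
histamine,C5H9N3,111.07965,biogenic amine
creatine,C4H9N3O2,131.06948,amino acid derivative
carnitine,C7H15NO3,161.10519,amino acid derivative
taurine,C2H7NO3S,125.01466,amino acid derivative
glutathione,C10H17N3O6S,307.08381,peptide
lactic acid,C3H6O3,90.03169,organic acid
citric acid,C6H8O7,192.02700,organic acid
succinic acid,C4H6O4,118.02661,organic acid
malic acid,C4H6O5,134.02152,organic acid
fumaric acid,C4H4O4,116.01096,organic acid
glucose,C6H12O6,180.06339,carbohydrate
hypoxanthine,C5H4N4O,136.03851,purine
inosine,C10H12N4O5,268.08077,nucleoside
adenine,C5H5N5,135.05450,purine
palmitic acid,C16H32O2,256.24023,fatty acid
stearic acid,C18H36O2,284.27153,fatty acid
oleic acid,C18H34O2,282.25588,fatty acid
linoleic acid,C18H32O2,280.24023,fatty acid
arachidonic acid,C20H32O2,304.24023,fatty acid
docosahexaenoic acid,C22H32O2,328.24023,fatty acid
docosapentaenoic acid,C22H34O2,330.25588,fatty acid
docosatetraenoic acid,C22H36O2,332.27153,fatty acid
PC(34:1),C42H82NO8P,759.57781,glycerophospholipid
PC(36:2),C44H84NO8P,785.59346,glycerophospholipid
PE(34:1),C39H76NO8P,717.53086,glycerophospholipid
PE(36:2),C41H78NO8P,743.54651,glycerophospholipid
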