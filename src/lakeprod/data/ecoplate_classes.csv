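substrate,chemical_class
beta-methyl-D-glucoside,carbohydrates
D-xylose,carbohydrates
i-erythritol,carbohydrates
D-mannitol,carbohydrates
N-acetyl-D-glucosamine,carbohydrates
D-cellobiose,carbohydrates
alpha-D-lactose,carbohydrates
glucose-1-phosphate,carbohydrates
D-L-alpha-glycerol phosphate,carbohydrates
pyruvic acid methyl ester,carboxylic acids
D-galactonic acid gamma-lactone,carboxylic acids
D-galacturonic acid,carboxylic acids
gamma-hydroxybutyric acid,carboxylic acids
D-glucosaminic acid,carboxylic acids
itaconic acid,carboxylic acids
alpha-ketobutyric acid,carboxylic acids
D-malic acid,carboxylic acids
L-arginine,amino acids
L-asparagine,amino acids
L-phenylalanine,amino acids
L-serine,amino acids
L-threonine,amino acids
glycyl-L-glutamic acid,amino acids
2-hydroxybenzoic acid,phenolic compounds
4-hydroxybenzoic acid,phenolic compounds
phenylethylamine,amines
putrescine,amines
tween 40,polymers
tween 80,polymers
alpha-cyclodextrin,polymers
glycogen,polymers
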