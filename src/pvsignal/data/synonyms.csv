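alias,canonical
valproic acid,valproic acid and sodium valproate
sodium valproate,valproic acid and sodium valproate
valproate sodium,valproic acid and sodium valproate
valproate semisodium,valproic acid and sodium valproate
valproate,valproic acid and sodium valproate
divalproex sodium,valproic acid and sodium valproate
clorazepate,clorazepate potassium
clorazepate dipotassium,clorazepate potassium
phenobarbital sodium,phenobarbital
phenobarbitone,phenobarbital
phenytoin sodium,phenytoin
fosphenytoin sodium,fosphenytoin
eslicarbazepine acetate,eslicarbazepine
gamma-aminobutyric acid,aminobutyric acid
methylphenobarbitone,methylphenobarbital
methsuximide,mesuximide
ezogabine,retigabine
fenfluramine hydrochloride,fenfluramine
tiagabine hydrochloride,tiagabine
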