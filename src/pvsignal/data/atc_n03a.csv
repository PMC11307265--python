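substance,atc_code,chemical_subgroup,era
Phenobarbital,N03AA02,barbiturates,old
Barbexaclone,N03AA04,barbiturates,old
Metharbital,N03AA30,barbiturates,old
Methylphenobarbital,N03AA01,barbiturates,old
Primidone,N03AA03,barbiturates,old
Clonazepam,N03AE01,benzodiazepines,old
Clorazepate potassium,N03AE02,benzodiazepines,old
Carbamazepine,N03AF01,carboxamides,old
Aminobutyric acid,N03AG03,fatty_acid_derivatives,old
Valproic acid and Sodium Valproate,N03AG01,fatty_acid_derivatives,old
Ethotoin,N03AB01,hydantoins,old
Mephenytoin,N03AB04,hydantoins,old
Phenytoin,N03AB02,hydantoins,old
Beclamide,N03AX30,other_antiepileptics,old
Phenacemide,N03AX07,other_antiepileptics,old
Pheneturide,N03AX13,other_antiepileptics,old
Sultiame,N03AX03,other_antiepileptics,old
Paramethadione,N03AC01,oxazolidines,old
Trimethadione,N03AC02,oxazolidines,old
Ethosuximide,N03AD01,succinimides,old
Mesuximide,N03AD03,succinimides,old
Phensuximide,N03AD02,succinimides,old
Clobazam,N03AE03,benzodiazepines,new
Eslicarbazepine,N03AF04,carboxamides,new
Oxcarbazepine,N03AF02,carboxamides,new
Rufinamide,N03AF03,carboxamides,new
Tiagabine,N03AG06,fatty_acid_derivatives,new
Vigabatrin,N03AG04,fatty_acid_derivatives,new
Fosphenytoin,N03AB05,hydantoins,new
Brivaracetam,N03AX23,other_antiepileptics,new
Cenobamate,N03AX25,other_antiepileptics,new
Felbamate,N03AX10,other_antiepileptics,new
Fenfluramine,N03AX26,other_antiepileptics,new
Gabapentin,N03AX12,other_antiepileptics,new
Lacosamide,N03AX18,other_antiepileptics,new
Lamotrigine,N03AX09,other_antiepileptics,new
Levetiracetam,N03AX14,other_antiepileptics,new
Perampanel,N03AX22,other_antiepileptics,new
Pregabalin,N03AX16,other_antiepileptics,new
Retigabine,N03AX21,other_antiepileptics,new
Stiripentol,N03AX17,other_antiepileptics,new
Topiramate,N03AX11,other_antiepileptics,new
Zonisamide,N03AX15,other_antiepileptics,new
Cannabidiol,N03AX24,other_antiepileptics,unclassified
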