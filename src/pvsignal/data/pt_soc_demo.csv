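pt,soc
Seizure,Nervous system disorders
Somnolence,Nervous system disorders
Dizziness,Nervous system disorders
Headache,Nervous system disorders
Tremor,Nervous system disorders
Epilepsy,Nervous system disorders
Status epilepticus,Nervous system disorders
Sudden unexplained death in epilepsy,Nervous system disorders
Drug ineffective,General disorders and administration site conditions
Fatigue,General disorders and administration site conditions
Pain,General disorders and administration site conditions
Pyrexia,General disorders and administration site conditions
Off label use,"Injury, poisoning and procedural complications"
Toxicity to various agents,"Injury, poisoning and procedural complications"
Drug interaction,"Injury, poisoning and procedural complications"
Overdose,"Injury, poisoning and procedural complications"
Rash,Skin and subcutaneous tissue disorders
Pruritus,Skin and subcutaneous tissue disorders
Alopecia,Skin and subcutaneous tissue disorders
Nausea,Gastrointestinal disorders
Vomiting,Gastrointestinal disorders
Diarrhoea,Gastrointestinal disorders
Anaemia,Blood and lymphatic system disorders
Thrombocytopenia,Blood and lymphatic system disorders
Agranulocytosis,Blood and lymphatic system disorders
Foetal anticonvulsant syndrome,"Congenital, familial and genetic disorders"
Foetal valproate syndrome,"Congenital, familial and genetic disorders"
Hepatic failure,Hepatobiliary disorders
Hepatitis,Hepatobiliary disorders
Cardiac arrest,Cardiac disorders
Bradycardia,Cardiac disorders
Depression,Psychiatric disorders
Insomnia,Psychiatric disorders
Aggression,Psychiatric disorders
Completed suicide,Psychiatric disorders
Weight increased,Investigations
Blood pressure increased,Investigations
Liver function test increased,Investigations
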