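raw,canonical,organ_system
Hepatic toxicity,Hepatotoxicity,Liver
Hepatotoxicity,Hepatotoxicity,Liver
Liver failure,Liver failure,Liver
Liver injury,Hepatotoxicity,Liver
Cardiotoxicity,Cardiotoxicity,Cardiovascular
Cardiac toxicity,Cardiotoxicity,Cardiovascular
Arrhythmia,Arrhythmia,Cardiovascular
Arrhythmias,Arrhythmia,Cardiovascular
QT prolongation,QT prolongation,Cardiovascular
Torsade de pointes,Torsade de pointes,Cardiovascular
Ventricular tachycardia,Ventricular tachycardia,Cardiovascular
Ventricular arrhythmias,Ventricular arrhythmia,Cardiovascular
Repolarization abnormalities,Repolarization abnormality,Cardiovascular
Myocardial infarction,Myocardial infarction,Cardiovascular
Neurotoxicity,Neurotoxicity,Neuropsychiatric
Abuse,Abuse,Neuropsychiatric
Abuse potential,Abuse,Neuropsychiatric
Central nervous system stimulation,CNS stimulation,Neuropsychiatric
Psychiatric disorders,Psychiatric disorder,Neuropsychiatric
Seizures,Seizure,Neuropsychiatric
Nephrotoxicity,Nephrotoxicity,Renal
Renal toxicity,Nephrotoxicity,Renal
Renal failure,Renal failure,Renal
Hematologic toxicity,Hematotoxicity,Hematologic
Agranulocytosis,Agranulocytosis,Hematologic
Aplastic anemia,Aplastic anemia,Hematologic
Thrombocytopenia,Thrombocytopenia,Hematologic
Anaphylaxis,Anaphylaxis,Immune
Hypersensitivity,Hypersensitivity,Immune
Stevens-Johnson syndrome,Stevens-Johnson syndrome,Dermatologic
Severe skin reactions,Severe skin reaction,Dermatologic
Carcinogenicity,Carcinogenicity,Oncologic
Teratogenicity,Teratogenicity,Reproductive
Rhabdomyolysis,Rhabdomyolysis,Musculoskeletal
Gastrointestinal toxicity,Gastrointestinal toxicity,Gastrointestinal
Pancreatitis,Pancreatitis,Gastrointestinal
Respiratory toxicity,Respiratory toxicity,Respiratory
Pulmonary hypertension,Pulmonary hypertension,Respiratory
Ototoxicity,Ototoxicity,Sensory
Visual disturbances,Visual disturbance,Sensory
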