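pt	soc
Hypokalaemia	Metabolism and nutrition disorders
Hypernatraemia	Metabolism and nutrition disorders
Blood sodium increased	Investigations
Blood pressure increased	Investigations
Constipation	Gastrointestinal disorders
Abdominal discomfort	Gastrointestinal disorders
Faeces hard	Gastrointestinal disorders
Ileus	Gastrointestinal disorders
Diarrhoea	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Dysphagia	Gastrointestinal disorders
Cardiac failure congestive	Cardiac disorders
Ventricular fibrillation	Cardiac disorders
Oedema peripheral	General disorders and administration site conditions
Fluid retention	General disorders and administration site conditions
Fatigue	General disorders and administration site conditions
Drug ineffective	General disorders and administration site conditions
Malaise	General disorders and administration site conditions
Headache	Nervous system disorders
Dizziness	Nervous system disorders
Rash	Skin and subcutaneous tissue disorders
Off label use	Injury, poisoning and procedural complications
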