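pt	pt_code	soc_name	soc_code
Nightmare	80000001	Psychiatric disorders	90000001
Aggression	80000002	Psychiatric disorders	90000001
Anxiety	80000003	Psychiatric disorders	90000001
Insomnia	80000004	Psychiatric disorders	90000001
Sleep terror	80000005	Psychiatric disorders	90000001
Suicidal ideation	80000006	Psychiatric disorders	90000001
Depression	80000007	Psychiatric disorders	90000001
Irritability	80000008	Psychiatric disorders	90000001
Abnormal dreams	80000009	Psychiatric disorders	90000001
Headache	80000010	Nervous system disorders	90000002
Dizziness	80000011	Nervous system disorders	90000002
Somnolence	80000012	Nervous system disorders	90000002
Tremor	80000013	Nervous system disorders	90000002
Paraesthesia	80000014	Nervous system disorders	90000002
Nausea	80000015	Gastrointestinal disorders	90000003
Vomiting	80000016	Gastrointestinal disorders	90000003
Diarrhoea	80000017	Gastrointestinal disorders	90000003
Abdominal pain	80000018	Gastrointestinal disorders	90000003
Dry mouth	80000019	Gastrointestinal disorders	90000003
Cough	80000020	Respiratory, thoracic and mediastinal disorders	90000004
Dyspnoea	80000021	Respiratory, thoracic and mediastinal disorders	90000004
Asthma	80000022	Respiratory, thoracic and mediastinal disorders	90000004
Epistaxis	80000023	Respiratory, thoracic and mediastinal disorders	90000004
Wheezing	80000024	Respiratory, thoracic and mediastinal disorders	90000004
Rash	80000025	Skin and subcutaneous tissue disorders	90000005
Pruritus	80000026	Skin and subcutaneous tissue disorders	90000005
Urticaria	80000027	Skin and subcutaneous tissue disorders	90000005
Angioedema	80000028	Skin and subcutaneous tissue disorders	90000005
Anaphylactic reaction	80000029	Immune system disorders	90000006
Hypersensitivity	80000030	Immune system disorders	90000006
Eosinophilic granulomatosis with polyangiitis	80000031	Immune system disorders	90000006
Pyrexia	80000032	General disorders and administration site conditions	90000007
Fatigue	80000033	General disorders and administration site conditions	90000007
Drug ineffective	80000034	General disorders and administration site conditions	90000007
Chest pain	80000035	General disorders and administration site conditions	90000007
Arthralgia	80000036	Musculoskeletal and connective tissue disorders	90000008
Myalgia	80000037	Musculoskeletal and connective tissue disorders	90000008
Muscle spasms	80000038	Musculoskeletal and connective tissue disorders	90000008
Hepatic enzyme increased	80000039	Investigations	90000009
Weight increased	80000040	Investigations	90000009
Blood pressure increased	80000041	Investigations	90000009
Palpitations	80000042	Cardiac disorders	90000010
Tachycardia	80000043	Cardiac disorders	90000010
Vision blurred	80000044	Eye disorders	90000011
Tinnitus	80000045	Ear and labyrinth disorders	90000012
Nasopharyngitis	80000046	Infections and infestations	90000013
Sinusitis	80000047	Infections and infestations	90000013
Influenza	80000048	Infections and infestations	90000013
Decreased appetite	80000049	Metabolism and nutrition disorders	90000014
Dehydration	80000050	Metabolism and nutrition disorders	90000014
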