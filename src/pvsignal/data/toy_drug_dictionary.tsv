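verbatim	canonical
MONTELUKAST	MONTELUKAST
Montelukast	MONTELUKAST
montelukast sodium	MONTELUKAST
MONTELUKAST SODIUM	MONTELUKAST
SINGULAIR	MONTELUKAST
Singulair	MONTELUKAST
MTK	MONTELUKAST
ASPIRIN	ASPIRIN
ACETYLSALICYLIC ACID	ASPIRIN
Aspirin	ASPIRIN
IBUPROFEN	IBUPROFEN
ADVIL	IBUPROFEN
MOTRIN	IBUPROFEN
PARACETAMOL	PARACETAMOL
ACETAMINOPHEN	PARACETAMOL
TYLENOL	PARACETAMOL
OMEPRAZOLE	OMEPRAZOLE
PRILOSEC	OMEPRAZOLE
ATORVASTATIN	ATORVASTATIN
LIPITOR	ATORVASTATIN
METFORMIN	METFORMIN
GLUCOPHAGE	METFORMIN
SALBUTAMOL	SALBUTAMOL
ALBUTEROL	SALBUTAMOL
VENTOLIN	SALBUTAMOL
FLUTICASONE	FLUTICASONE
FLOVENT	FLUTICASONE
CETIRIZINE	CETIRIZINE
ZYRTEC	CETIRIZINE
UNSPECIFIED CO-MEDICATION	UNSPECIFIED CO-MEDICATION
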