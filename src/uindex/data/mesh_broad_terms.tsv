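term	head_term
Biology	Biology
Anatomy	Biology
Biochemistry	Biology
Biophysics	Biology
Botany	Biology
Cell Biology	Biology
Cytology	Biology
Ecology	Biology
Embryology	Biology
Genetics	Biology
Genetics, Medical	Biology
Microbiology	Biology
Molecular Biology	Biology
Parasitology	Biology
Physiology	Biology
Virology	Biology
Zoology	Biology
Developmental Biology	Biology
Neurosciences	Biology
Medicine	Medicine
Allergy and Immunology	Medicine
Anesthesiology	Medicine
Cardiology	Medicine
Dermatology	Medicine
Emergency Medicine	Medicine
Endocrinology	Medicine
Family Practice	Medicine
Gastroenterology	Medicine
General Surgery	Medicine
Geriatrics	Medicine
Gynecology	Medicine
Hematology	Medicine
Internal Medicine	Medicine
Neoplasms	Medicine
Nephrology	Medicine
Neurology	Medicine
Obstetrics	Medicine
Oncology	Medicine
Ophthalmology	Medicine
Orthopedics	Medicine
Otolaryngology	Medicine
Pathology	Medicine
Pediatrics	Medicine
Pharmacology	Medicine
Psychiatry	Medicine
Pulmonary Medicine	Medicine
Radiology	Medicine
Rheumatology	Medicine
Urology	Medicine
Vascular Diseases	Medicine
Computational Biology	Computational Biology
Genomics	Computational Biology
Proteomics	Computational Biology
Systems Biology	Computational Biology
Medical Informatics	Medical Informatics
Medical Informatics Applications	Medical Informatics
Medical Records Systems, Computerized	Medical Informatics
Nursing Informatics	Medical Informatics
Public Health Informatics	Medical Informatics
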