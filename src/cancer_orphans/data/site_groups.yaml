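# Mapping of the 35 exhaustive, mutually exclusive cancer-site labels (female
# deaths) to the 14 reporting groups.  Editable: site-level mortality inputs
# must use exactly these site labels; every site must map to exactly one of
# the 14 group labels.
Lip, oral cavity: Head and Neck
Salivary glands: Head and Neck
Oropharynx: Head and Neck
Nasopharynx: Head and Neck
Hypopharynx: Head and Neck
Other pharynx: Head and Neck
Larynx: Head and Neck
Oesophagus: Upper gastrointestinal
Stomach: Upper gastrointestinal
Liver: Upper gastrointestinal
Gallbladder: Upper gastrointestinal
Pancreas: Upper gastrointestinal
Colon: Lower gastrointestinal
Rectum: Lower gastrointestinal
Anus: Lower gastrointestinal
Trachea, bronchus and lung: Respiratory
Mesothelioma: Respiratory
Melanoma of skin: Skin cancer
Non-melanoma skin: Skin cancer
Kaposi sarcoma: Kaposi Sarcoma
Breast: Breast
Cervix uteri: Cervical
Corpus uteri: Other female-specific
Ovary: Other female-specific
Vulva: Other female-specific
Vagina: Other female-specific
Kidney: Genitourinary
Bladder: Genitourinary
Brain, central nervous system: Brain and nervous system
Thyroid: Thyroid
Hodgkin lymphoma: Hematological
Non-Hodgkin lymphoma: Hematological
Multiple myeloma: Hematological
Leukaemia: Hematological
Other and unspecified: Other
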