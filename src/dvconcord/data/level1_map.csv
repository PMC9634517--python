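kind,key_start,key_end,level1
range,F00,F09,Mental disorders due to known physiological conditions
range,F10,F19,Mental and behavioral disorders due to psychoactive substance use
range,F20,F29,"Schizophrenia, schizotypal, delusional, and other nonmood psychotic disorders"
range,F30,F39,Mood (affective) disorders
range,F40,F48,"Anxiety, dissociative, stress related, somatoform, and other nonpsychotic mental disorders"
range,F50,F59,Behavioral syndromes associated with physiological disturbances and physical factors
range,F60,F69,Disorders of adult personality and behavior
range,F70,F79,Intellectual disability
range,F80,F89,Pervasive and specific developmental disorders
range,F90,F98,Behavioral and emotional disorders with onset usually occurring in childhood and adolescence
range,F99,F99,Unspecified mental disorder
range,G10,G14,Systematic atrophies primarily affecting the central nervous system
range,G30,G32,Other degenerative diseases of the nervous system
range,G00,G99,Diseases of the nervous system
range,Q90,Q99,"Chromosomal abnormalities, not elsewhere classified"
range,R40,R46,"Symptoms and signs involving cognition, perception, emotional state, and behavior"
range,S06,S06,Traumatic brain injury
range,T14,T14,Injury of unspecified body region
range,X60,X84,Intentional self-harm
token,UNSPECIFIED_MI,UNSPECIFIED_MI,Unspecified mental disorder
token,SUBSTANCE_ABUSE,SUBSTANCE_ABUSE,Substance abuse
token,DRUG_INDUCED,DRUG_INDUCED,Unspecified drug-induced disorders
token,RX_ABUSE,RX_ABUSE,Drug prescription abuse
token,MED_ANTIDEPRESSANT,MED_ANTIDEPRESSANT,Medications: antidepressants
token,MED_ANTIPSYCHOTIC,MED_ANTIPSYCHOTIC,Medications (antipsychotics)
token,MED_ANXIOLYTIC,MED_ANXIOLYTIC,Medications for anxiety
token,MED_NEUROLEPTIC,MED_NEUROLEPTIC,Medications (neuroleptics)
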