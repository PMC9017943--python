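column,type,required_column,description
record_id,string,no,Stable identifier of one administration row; assigned at load time when absent
center_id,string,yes,Identifier of the medical center that produced the record
center_category,string,no,"Center category: GH_NFPH, UH, CCC or PH"
center_region,string,no,"Center region: North, East, SouthEast, SouthWest, West or ParisArea"
patient_id,string,yes,Patient identifier; unique within a center only
birth_year,integer,no,Year of birth
gender,string,no,F or M (free text mapped through the gender synonym table)
weight_kg,number,no,Patient weight in kilograms
height_cm,number,no,Patient height in centimeters
ecog,integer,no,ECOG performance status 0-4
diagnosis,string,no,"Primary cancer: breast_cancer, lung_cancer or other (synonyms mapped)"
disease_stage,string,no,"Disease stage: early, locally_advanced or metastatic (synonyms mapped)"
metastasis_sites,string,no,Semicolon-separated metastatic site codes
oncogenic_driver,string,no,Oncogenic driver code (e.g. HER2+ or EGFR)
drug_raw,string,yes,Drug name exactly as entered (INN or brand; any case or accents)
drug_inn,string,no,Standardized International Nonproprietary Name (filled by codification)
drug_brand,string,no,Brand name as entered
drug_match_status,string,no,"Codification status: matched, inn_only, brand_conflict or unknown_drug"
dose_mg,number,yes,Administered dose in mg; must be positive
administration_date,date,yes,Calendar date of the administration (ISO-8601); rows without it are fatal
treatment_line,integer,no,Treatment line (positive integer)
cycle_number,integer,no,Cycle number within the regimen (positive integer)
frequency_days,integer,no,Days between cycles
regimen_label,string,no,Free-text regimen/protocol label
estimated_duration_days,integer,no,Estimated duration of the regimen in days
response,string,no,"Disease assessment result: CR, PR, SD or PD (synonyms mapped)"
response_date,date,no,Date of the disease assessment
discontinuation_motive,string,no,Free-text discontinuation motive
discontinuation_date,date,no,Date of treatment discontinuation
trial_name,string,no,Clinical trial name or 'none'
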