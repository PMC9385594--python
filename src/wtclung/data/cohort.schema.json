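{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Cohort CSV row",
  "description": "One participant of the responder cohort. Dates are ISO-8601 (YYYY-MM-DD); booleans are 0/1; missing values are empty cells.",
  "type": "object",
  "required": ["id", "enrollment_date", "age_at_enrollment", "sex",
               "race_ethnicity", "education", "smoking_status",
               "cigarettes_per_day", "smoking_duration", "prior_cancer",
               "wtc_exposure_level", "last_encounter_date", "lung_cancer"],
  "properties": {
    "id": {"type": "string"},
    "enrollment_date": {"type": "string", "format": "date"},
    "age_at_enrollment": {"type": "number", "minimum": 0},
    "sex": {"enum": ["female", "male"]},
    "race_ethnicity": {"enum": ["nl_white", "nl_black", "latino", "asian", "multiracial", "other"]},
    "education": {"enum": ["lt_hs", "hs_grad", "some_college", "college_grad", "grad_school", "unknown", null]},
    "bmi": {"type": ["number", "null"], "description": "kg/m^2"},
    "copd": {"type": ["boolean", "null"]},
    "fev1": {"type": ["number", "null"], "description": "liters"},
    "fvc": {"type": ["number", "null"], "description": "liters"},
    "smoking_status": {"enum": ["never", "former", "current"]},
    "cigarettes_per_day": {"type": "number", "minimum": 0},
    "smoking_duration": {"type": "number", "minimum": 0, "description": "years"},
    "pack_years": {"type": ["number", "null"], "description": "cigarettes_per_day/20 x smoking_duration"},
    "years_since_quit": {"type": ["number", "null"], "description": "former smokers only"},
    "family_history_lung_cancer": {"type": ["boolean", "null"]},
    "prior_cancer": {"type": "boolean"},
    "wtc_exposure_level": {"enum": ["low", "intermediate", "high", "missing"]},
    "wtc_arrival_48h": {"type": ["boolean", "null"]},
    "wtc_duration_gt60d": {"type": ["boolean", "null"]},
    "occ_asbestos": {"type": "boolean"},
    "occ_cadmium": {"type": "boolean"},
    "occ_diesel": {"type": "boolean"},
    "occ_nondiesel_fumes": {"type": "boolean"},
    "occ_general_dust": {"type": "boolean"},
    "occ_mineral_dust": {"type": "boolean"},
    "occ_wood_dust": {"type": "boolean"},
    "occ_silica": {"type": "boolean"},
    "occ_fiberglass": {"type": "boolean"},
    "occ_industrial_solutions": {"type": "boolean"},
    "occ_welding": {"type": "boolean"},
    "occ_any_moderate_significant": {"type": "boolean"},
    "last_encounter_date": {"type": "string", "format": "date"},
    "lung_cancer": {"type": "boolean"},
    "lung_cancer_date": {"type": ["string", "null"], "format": "date",
                         "description": "required iff lung_cancer"}
  }
}
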