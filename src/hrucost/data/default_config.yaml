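measures:
- measure_id: ed_visits
  label: Emergency department visits (hospital-based)
  domain: general_medical
  perspective: healthcare_sector
  structure: single_count
  unit: visits
  costable: true
- measure_id: hospitalizations
  label: Hospitalizations
  domain: general_medical
  perspective: healthcare_sector
  structure: frequency_duration
  unit: days
  costable: true
- measure_id: hospital_clinic_visits
  label: Hospital clinic / outpatient department visits
  domain: general_medical
  perspective: healthcare_sector
  structure: provider_visits
  unit: visits
  costable: true
- measure_id: community_clinic_visits
  label: Community clinic / neighborhood health center visits
  domain: general_medical
  perspective: healthcare_sector
  structure: provider_visits
  unit: visits
  costable: true
- measure_id: physician_visits
  label: Physician visits
  domain: general_medical
  perspective: healthcare_sector
  structure: provider_visits
  unit: visits
  costable: true
- measure_id: mh_visits_psych
  label: Mental healthcare provider visits (psychological / emotional issues)
  domain: general_medical
  perspective: healthcare_sector
  structure: provider_visits
  unit: visits
  costable: true
- measure_id: mh_visits_medmgmt
  label: Mental healthcare provider visits (medication management)
  domain: general_medical
  perspective: healthcare_sector
  structure: provider_visits
  unit: visits
  costable: true
- measure_id: dental_visits
  label: Dental care visits
  domain: general_medical
  perspective: none
  structure: single_count
  unit: visits
  costable: false
- measure_id: emergency_dental_visits
  label: Emergency dental care visits
  domain: general_medical
  perspective: none
  structure: single_count
  unit: visits
  costable: false
- measure_id: trauma_counseling_visits
  label: Provider visits for trauma counseling
  domain: general_medical
  perspective: none
  structure: single_count
  unit: visits
  costable: false
- measure_id: shelter_nights
  label: Nights in homeless or emergency shelter
  domain: general_medical
  perspective: none
  structure: single_count
  unit: nights
  costable: false
- measure_id: case_manager_visits
  label: Case managers or case workers
  domain: general_medical
  perspective: none
  structure: single_count
  unit: visits
  costable: false
- measure_id: times_treated_alcohol
  label: Times treated for alcohol use
  domain: sud_treatment
  perspective: none
  structure: single_count
  unit: episodes
  costable: false
- measure_id: times_treated_sud
  label: Times treated for substance use disorder
  domain: sud_treatment
  perspective: none
  structure: single_count
  unit: episodes
  costable: false
- measure_id: residential_treatment
  label: Residential drug or alcohol treatment facility / detoxification hospital
  domain: sud_treatment
  perspective: healthcare_sector
  structure: frequency_duration
  unit: days
  costable: true
- measure_id: sud_provider_visits
  label: Alcohol / drug treatment provider visits
  domain: sud_treatment
  perspective: healthcare_sector
  structure: provider_visits
  unit: visits
  costable: true
- measure_id: sud_provider_visits_medmgmt
  label: Alcohol / drug treatment provider visits (medication management)
  domain: sud_treatment
  perspective: healthcare_sector
  structure: provider_visits
  unit: visits
  costable: true
- measure_id: rx_med_aud
  label: Prescribed medication for alcohol use disorder
  domain: medications
  perspective: none
  structure: binary
  unit: indicator
  costable: false
- measure_id: rx_med_sud
  label: Prescribed medication for substance use disorder
  domain: medications
  perspective: none
  structure: binary
  unit: indicator
  costable: false
- measure_id: money_spent_drugs
  label: Money spent on drugs
  domain: spending
  perspective: societal
  structure: dollars
  unit: USD
  costable: true
- measure_id: money_spent_alcohol
  label: Money spent on alcohol
  domain: spending
  perspective: societal
  structure: dollars
  unit: USD
  costable: true
- measure_id: days_alcohol_problems
  label: Days experiencing alcohol problems
  domain: problem_days
  perspective: societal
  structure: single_count
  unit: days
  costable: true
- measure_id: days_drug_problems
  label: Days experiencing drug problems
  domain: problem_days
  perspective: societal
  structure: single_count
  unit: days
  costable: true
studies:
- study_id: PACTO
  n_participants: 409
  max_recorded_events: 5
  recall_days:
    ed_visits: 182
    hospitalizations: 182
    hospital_clinic_visits: 182
    community_clinic_visits: 182
    physician_visits: 182
    mh_visits_psych: 182
    mh_visits_medmgmt: 182
    dental_visits: 182
    emergency_dental_visits: 182
    trauma_counseling_visits: 182
    shelter_nights: 182
    case_manager_visits: 182
    times_treated_alcohol: lifetime
    times_treated_sud: lifetime
    residential_treatment: 182
    sud_provider_visits: 182
    sud_provider_visits_medmgmt: 182
    rx_med_aud: 30
    rx_med_sud: 30
    money_spent_drugs: 30
    money_spent_alcohol: 30
    days_alcohol_problems: 30
    days_drug_problems: 30
- study_id: RETAIN
  n_participants: 360
  max_recorded_events: 5
  recall_days:
    ed_visits: 182
    hospitalizations: 182
    hospital_clinic_visits: 182
    community_clinic_visits: 182
    physician_visits: 182
    mh_visits_psych: 182
    mh_visits_medmgmt: 182
    dental_visits: 182
    emergency_dental_visits: 182
    trauma_counseling_visits: 182
    shelter_nights: 182
    case_manager_visits: 182
    times_treated_alcohol: lifetime
    times_treated_sud: lifetime
    residential_treatment: 182
    sud_provider_visits: 182
    sud_provider_visits_medmgmt: 182
    rx_med_aud: 30
    rx_med_sud: 30
    money_spent_drugs: 30
    money_spent_alcohol: 30
    days_alcohol_problems: 30
    days_drug_problems: 30
- study_id: BRIGHT2
  n_participants: 99
  max_recorded_events: 5
  recall_days:
    ed_visits: 365
    hospitalizations: 365
    hospital_clinic_visits: 365
    community_clinic_visits: 365
    physician_visits: 365
    mh_visits_psych: 365
    mh_visits_medmgmt: 365
    case_manager_visits: 365
    times_treated_alcohol: lifetime
    times_treated_sud: lifetime
    residential_treatment: 365
    sud_provider_visits: 365
    sud_provider_visits_medmgmt: 365
    rx_med_aud: lifetime
    rx_med_sud: lifetime
mcfs:
- measure_id: ed_visits
  unit_cost: 989.0
  price_year: 2017
  source: Medical Expenditure Panel Survey
- measure_id: hospitalizations
  unit_cost: 4255.0
  price_year: 2017
  source: Medical Expenditure Panel Survey
- measure_id: residential_treatment
  unit_cost: 126.0
  price_year: 2017
  source: ADSS cost study (SAMHSA 1997)
- measure_id: hospital_clinic_visits
  unit_cost: 1128.0
  price_year: 2017
  source: Medical Expenditure Panel Survey
- measure_id: community_clinic_visits
  unit_cost: 1128.0
  price_year: 2017
  source: Medical Expenditure Panel Survey
- measure_id: physician_visits
  unit_cost: 1128.0
  price_year: 2017
  source: Medical Expenditure Panel Survey
- measure_id: mh_visits_psych
  unit_cost: 85.0
  price_year: 2017
  source: Medicare physician fee schedule
  code: '90834'
- measure_id: mh_visits_medmgmt
  unit_cost: 44.0
  price_year: 2017
  source: Medicare physician fee schedule
  code: '99212'
- measure_id: sud_provider_visits
  unit_cost: 153.0
  price_year: 2017
  source: ADSS cost study (SAMHSA 1997)
- measure_id: sud_provider_visits_medmgmt
  unit_cost: 44.0
  price_year: 2017
  source: ADSS cost study (SAMHSA 1997)
- measure_id: days_alcohol_problems
  unit_cost: 19.0
  price_year: 2017
  source: McCollister, Yang (pooled problem-day values)
- measure_id: days_drug_problems
  unit_cost: 19.0
  price_year: 2017
  source: McCollister, Yang (pooled problem-day values)
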