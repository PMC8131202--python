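{
  "alpha_fed": -0.9785180853283765,
  "intercepts": {
    "breastfeeding_at_discharge": 0.03513828019169573,
    "culture_positive_late_onset": -5.936151381091703,
    "hypoglycaemia": -1.8576857356901981,
    "pragmatic_late_onset_infection": -1.5035667524645122,
    "pragmatic_nec": -5.136939659824881,
    "survival_to_discharge": 2.7979346090679527
  },
  "params": {
    "confounding_strength": 1.0,
    "missingness": {
      "admission_glucose": 0.12,
      "admission_heart_rate": 0.1,
      "admission_mean_bp": 0.15,
      "admission_spo2": 0.1,
      "admission_temperature": 0.12,
      "apgar_1": 0.08,
      "apgar_5": 0.08,
      "caesarean_delivery": 0.04,
      "cord_arterial_ph": 0.28,
      "deprivation_decile": 0.15,
      "inotropes_day1": 0.04,
      "maternal_age": 0.05,
      "maternal_diabetes": 0.05,
      "maternal_ethnicity": 0.16,
      "maternal_fever": 0.12,
      "maternal_hypothyroidism": 0.07,
      "maternal_smoking": 0.14,
      "mechanical_ventilation_day1": 0.03,
      "membrane_rupture_hours": 0.2,
      "primiparous": 0.06,
      "suspected_chorioamnionitis": 0.18,
      "time_to_first_breath_min": 0.18
    },
    "n_babies": 10,
    "outcome_base_rates": {
      "breastfeeding_at_discharge": 0.462,
      "culture_positive_late_onset": 0.005,
      "hypoglycaemia": 0.2,
      "pragmatic_late_onset_infection": 0.259,
      "pragmatic_nec": 0.011,
      "survival_to_discharge": 0.903
    },
    "p_fed_target": 0.311,
    "seed": 183,
    "true_effects": {},
    "year_range": [
      2010,
      2017
    ]
  },
  "true_effects": {
    "breastfeeding_at_discharge": 0.0,
    "central_line_days": 0.0,
    "culture_positive_late_onset": 0.0,
    "first_maternal_milk_day": 0.0,
    "hypoglycaemia": 0.0,
    "length_of_stay": 0.0,
    "onset_of_breastfeeding": 0.0,
    "parenteral_nutrition_days": 0.0,
    "pragmatic_late_onset_infection": 0.0,
    "pragmatic_nec": 0.0,
    "survival_to_discharge": 0.0,
    "weight_sd_score": 0.0
  }
}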