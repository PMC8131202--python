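infant_id,birth_year,gestational_age_weeks,birthweight_g,sex,multiple_birth,maternal_age,membrane_rupture_hours,maternal_fever,suspected_chorioamnionitis,maternal_smoking,maternal_ethnicity,deprivation_decile,maternal_hypothyroidism,maternal_diabetes,caesarean_delivery,primiparous,apgar_1,apgar_5,chest_compressions,resus_drugs,intubated_at_resus,cord_arterial_ph,time_to_first_breath_min,admission_mean_bp,admission_glucose,admission_heart_rate,admission_spo2,admission_temperature,early_onset_culture_positive,inotropes_day1,mechanical_ventilation_day1,nitric_oxide_day1,postnatal_transfer_24h,network,parenteral_nutrition_day1,death_flag,death_day,discharge_day,nec_diagnosis_recorded,severe_nec_confirmed,blood_cultures,breastfeeding_at_discharge,discharge_weight_g,hypoglycaemia_recorded
B000001,2017,40.5,3682.0,male,0.0,28.0,,0.0,1.0,0.0,,8.0,0.0,0.0,0.0,0.0,6.0,5.0,0.0,1.0,0.0,6.835,,38.2,,102.0,95.0,35.3,0.0,0.0,1.0,0.0,0.0,N08,1.0,0.0,,18,0.0,0.0,,0.0,3396.0,0.0
B000002,2017,37.9,2931.0,male,0.0,27.0,6.8,0.0,,0.0,white,5.0,0.0,0.0,0.0,1.0,2.0,6.0,0.0,1.0,1.0,,4.5,46.9,,127.0,95.0,35.6,0.0,0.0,0.0,0.0,0.0,N10,0.0,0.0,,10,0.0,0.0,4:0,0.0,,1.0
B000003,2017,39.5,2794.0,female,0.0,32.0,0.8,0.0,1.0,0.0,white,7.0,0.0,0.0,1.0,,1.0,4.0,1.0,1.0,1.0,6.94,,36.7,5.9,140.0,93.0,34.7,0.0,0.0,1.0,0.0,1.0,N06,1.0,0.0,,16,0.0,0.0,,0.0,3793.0,0.0
B000004,2015,38.3,2382.0,male,0.0,29.0,3.4,0.0,,,,7.0,0.0,0.0,1.0,0.0,3.0,4.0,1.0,1.0,0.0,7.075,7.2,34.7,5.1,138.0,93.0,36.6,0.0,1.0,1.0,0.0,1.0,N10,1.0,0.0,,8,0.0,0.0,,0.0,3207.0,0.0
B000005,2016,39.5,3358.0,female,0.0,23.0,4.7,,0.0,0.0,,10.0,0.0,0.0,0.0,0.0,4.0,6.0,0.0,0.0,1.0,6.976,5.1,36.9,3.7,110.0,,35.7,0.0,1.0,0.0,0.0,1.0,N03,0.0,0.0,,16,0.0,0.0,,1.0,3367.0,0.0
B000006,2010,41.4,4621.0,male,0.0,36.0,2.1,0.0,0.0,0.0,white,10.0,0.0,1.0,0.0,0.0,8.0,10.0,0.0,0.0,0.0,7.115,1.9,45.5,4.7,141.0,,,0.0,0.0,0.0,0.0,0.0,N05,1.0,0.0,,13,0.0,0.0,3:0,0.0,4151.0,0.0
B000007,2013,41.2,3621.0,male,0.0,32.0,,0.0,0.0,0.0,white,4.0,0.0,,1.0,0.0,5.0,5.0,0.0,0.0,0.0,7.257,7.6,45.0,3.6,113.0,97.0,,0.0,0.0,0.0,0.0,0.0,N02,1.0,0.0,,8,0.0,0.0,,1.0,4277.0,0.0
B000008,2014,42.2,4079.0,female,0.0,40.0,5.6,0.0,0.0,0.0,,3.0,0.0,0.0,1.0,1.0,0.0,1.0,1.0,0.0,1.0,6.747,,42.3,5.6,113.0,96.0,35.1,0.0,1.0,1.0,1.0,0.0,N03,1.0,0.0,,11,0.0,0.0,,0.0,4381.0,1.0
B000009,2015,40.5,4710.0,male,0.0,39.0,,0.0,0.0,0.0,white,10.0,0.0,0.0,0.0,1.0,6.0,6.0,0.0,0.0,0.0,7.157,,52.9,5.3,137.0,91.0,35.5,0.0,0.0,1.0,0.0,1.0,N08,1.0,0.0,,9,0.0,0.0,,0.0,,0.0
B000010,2014,38.2,3516.0,male,0.0,38.0,10.3,0.0,0.0,,white,,0.0,0.0,1.0,1.0,,3.0,0.0,0.0,1.0,7.02,3.5,38.1,1.8,99.0,95.0,35.5,0.0,0.0,1.0,0.0,1.0,N05,1.0,0.0,,7,0.0,0.0,5:0,0.0,3741.0,0.0
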