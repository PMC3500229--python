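person_id,adjudicated_status,adjudicated_subtype
M001,incident_diabetes,type1
M002,incident_diabetes,type1
M003,incident_diabetes,type1
M004,incident_diabetes,type1
M005,incident_diabetes,type1
M006,incident_diabetes,type1
M007,incident_diabetes,type1
M008,incident_diabetes,type1
M009,incident_diabetes,type1
M010,incident_diabetes,type1
M011,incident_diabetes,type1
M012,incident_diabetes,type1
M013,incident_diabetes,type2
M014,incident_diabetes,type2
M015,prevalent_diabetes,not_applicable
M016,incident_diabetes,type1
M017,incident_diabetes,type2
M018,incident_diabetes,type2
M019,incident_diabetes,type2
M020,incident_diabetes,type2
M021,incident_diabetes,type2
M022,incident_diabetes,type2
M023,incident_diabetes,type2
M024,incident_diabetes,type2
M025,incident_diabetes,type2
M026,incident_diabetes,type2
M027,incident_diabetes,type2
M028,incident_diabetes,type2
M029,incident_diabetes,type2
M030,incident_diabetes,type2
M031,incident_diabetes,type2
M032,incident_diabetes,type2
M033,incident_diabetes,type2
M034,incident_diabetes,type2
M035,incident_diabetes,type2
M036,incident_diabetes,type2
M037,incident_diabetes,type2
M038,incident_diabetes,type2
M039,incident_diabetes,type2
M040,incident_diabetes,unspecified
M041,incident_diabetes,unspecified
M042,incident_diabetes,unspecified
M043,subthreshold_hyperglycemia,not_applicable
M044,subthreshold_hyperglycemia,not_applicable
M045,subthreshold_hyperglycemia,not_applicable
M046,pcos,not_applicable
N001,incident_diabetes,unspecified
N002,possible_diabetes,not_applicable
N003,subthreshold_hyperglycemia,not_applicable
N004,miscoded,not_applicable
N005,incident_diabetes,unspecified
N006,incident_diabetes,unspecified
N007,incident_diabetes,unspecified
N008,incident_diabetes,unspecified
N009,possible_diabetes,not_applicable
N010,subthreshold_hyperglycemia,not_applicable
N011,subthreshold_hyperglycemia,not_applicable
N012,subthreshold_hyperglycemia,not_applicable
N013,subthreshold_hyperglycemia,not_applicable
N014,lab_rule_out,not_applicable
N015,miscoded,not_applicable
N016,prevalent_diabetes,not_applicable
N017,possible_diabetes,not_applicable
N018,possible_diabetes,not_applicable
N019,possible_diabetes,not_applicable
N020,possible_diabetes,not_applicable
N021,possible_diabetes,not_applicable
N022,subthreshold_hyperglycemia,not_applicable
N023,subthreshold_hyperglycemia,not_applicable
N024,pcos,not_applicable
N025,pcos,not_applicable
N026,pcos,not_applicable
N027,pcos,not_applicable
N028,pcos,not_applicable
N029,pcos,not_applicable
N030,lab_rule_out,not_applicable
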