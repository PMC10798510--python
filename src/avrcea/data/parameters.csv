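arm,stratum,name,mean,low,high,dist,units
SUAVR,overall,p_complication,0.2901,0.2753,0.3049,beta,probability
CAVR,overall,p_complication,0.2795,0.2652,0.2937,beta,probability
SUAVR,overall,p_death_given_nocomp,0.0294,0.0279,0.0309,beta,probability
CAVR,overall,p_death_given_nocomp,0.0303,0.0288,0.0318,beta,probability
SUAVR,overall,p_death_given_comp,0.1252,0.1188,0.1315,beta,probability
CAVR,overall,p_death_given_comp,0.1290,0.1224,0.1356,beta,probability
SUAVR,isolated,p_complication,0.2769,0.2628,0.2910,beta,probability
CAVR,isolated,p_complication,0.2636,0.2502,0.2771,beta,probability
SUAVR,isolated,p_death_given_nocomp,0.0117,0.0111,0.0122,beta,probability
CAVR,isolated,p_death_given_nocomp,0.0125,0.0119,0.0131,beta,probability
SUAVR,isolated,p_death_given_comp,0.0000,0.0000,0.0000,fixed,probability
CAVR,isolated,p_death_given_comp,0.0000,0.0000,0.0000,fixed,probability
SUAVR,combined,p_complication,0.3096,0.2938,0.3254,beta,probability
CAVR,combined,p_complication,0.2975,0.2823,0.3127,beta,probability
SUAVR,combined,p_death_given_nocomp,0.0462,0.0439,0.0486,beta,probability
CAVR,combined,p_death_given_nocomp,0.0471,0.0447,0.0495,beta,probability
SUAVR,combined,p_death_given_comp,0.2311,0.2193,0.2428,beta,probability
CAVR,combined,p_death_given_comp,0.2353,0.2233,0.2473,beta,probability
SUAVR,all,p_death_1y,0.0384,0.0364,0.0404,beta,probability
CAVR,all,p_death_1y,0.0343,0.0326,0.0361,beta,probability
SUAVR,all,p_stroke,0.0214,0.0203,0.0225,beta,probability
CAVR,all,p_stroke,0.0197,0.0187,0.0207,beta,probability
SUAVR,all,p_af,0.0393,0.0373,0.0413,beta,probability
CAVR,all,p_af,0.0922,0.0875,0.0969,beta,probability
SUAVR,all,p_bleed,0.0327,0.0310,0.0344,beta,probability
CAVR,all,p_bleed,0.0338,0.0321,0.0355,beta,probability
SUAVR,all,p_aki,0.0218,0.0207,0.0229,beta,probability
CAVR,all,p_aki,0.0207,0.0196,0.0218,beta,probability
SUAVR,all,p_ppm,0.0405,0.0384,0.0426,beta,probability
CAVR,all,p_ppm,0.0289,0.0274,0.0304,beta,probability
SUAVR,all,p_pvl,0.0858,0.0814,0.0902,beta,probability
CAVR,all,p_pvl,0.0289,0.0274,0.0304,beta,probability
SUAVR,all,cost_valve,458818,367055,550582,gamma,THB
CAVR,all,cost_valve,137186,109749,164623,gamma,THB
SUAVR,all,cost_valve_materials,36889,29511,44267,gamma,THB
CAVR,all,cost_valve_materials,41526,33221,49832,gamma,THB
SUAVR,all,cost_anesthesia_operation,146881,117504,176257,gamma,THB
CAVR,all,cost_anesthesia_operation,149003,119202,178803,gamma,THB
SUAVR,all,cost_drugs,73172,53331,93013,gamma,THB
CAVR,all,cost_drugs,76813,61519,92108,gamma,THB
SUAVR,all,cost_labs,66276,55129,77422,gamma,THB
CAVR,all,cost_labs,69713,60600,78826,gamma,THB
SUAVR,all,cost_hospital_stay,19961,15969,23953,gamma,THB
CAVR,all,cost_hospital_stay,20500,16400,24600,gamma,THB
SUAVR,all,cost_imaging,20342,16135,24549,gamma,THB
CAVR,all,cost_imaging,15815,12361,19270,gamma,THB
SUAVR,all,cost_special_diagnosis,13080,11686,14473,gamma,THB
CAVR,all,cost_special_diagnosis,10486,8999,11973,gamma,THB
SUAVR,all,cost_instruments,77406,66823,87989,gamma,THB
CAVR,all,cost_instruments,77500,67298,87702,gamma,THB
SUAVR,all,cost_blood,43429,35728,51129,gamma,THB
CAVR,all,cost_blood,51637,43990,59284,gamma,THB
SUAVR,all,cost_rehabilitation,2449,1929,2969,gamma,THB
CAVR,all,cost_rehabilitation,2060,1600,2520,gamma,THB
both,all,cost_followup_outpatient,3769,3015,4523,gamma,THB
both,all,cost_inpatient_stroke,77379,61903,92854,gamma,THB
both,all,cost_inpatient_af,27841,22273,33409,gamma,THB
both,all,cost_inpatient_bleed,42947,34358,51537,gamma,THB
both,all,cost_inpatient_aki,40175,32140,48210,gamma,THB
both,all,cost_inpatient_ppm,292009,233607,350411,gamma,THB
both,all,cost_inpatient_pvl,406704,325363,488045,gamma,THB
both,all,cost_outpatient_stroke,12277,9821,14732,gamma,THB
both,all,cost_outpatient_af,5627,4501,6752,gamma,THB
both,all,cost_outpatient_bleed,5382,4306,6459,gamma,THB
both,all,cost_outpatient_aki,4046,3237,4856,gamma,THB
both,all,cost_outpatient_ppm,4248,3399,5098,gamma,THB
both,all,cost_outpatient_pvl,2627,2102,3153,gamma,THB
SUAVR,all,cost_nonmed_admission_transport,1295,1036,1554,gamma,THB
CAVR,all,cost_nonmed_admission_transport,1467,1173,1760,gamma,THB
SUAVR,all,cost_nonmed_admission_food,5961,4769,7153,gamma,THB
CAVR,all,cost_nonmed_admission_food,6831,5465,8197,gamma,THB
SUAVR,all,cost_nonmed_admission_accommodation,0,0,0,fixed,THB
CAVR,all,cost_nonmed_admission_accommodation,1603,1282,1923,gamma,THB
SUAVR,all,cost_nonmed_admission_informal_care,20010,16008,24012,gamma,THB
CAVR,all,cost_nonmed_admission_informal_care,17795,14236,21355,gamma,THB
SUAVR,all,cost_nonmed_followup_transport,5108,4086,6130,gamma,THB
CAVR,all,cost_nonmed_followup_transport,5790,4632,6948,gamma,THB
SUAVR,all,cost_nonmed_followup_food,1620,1296,1944,gamma,THB
CAVR,all,cost_nonmed_followup_food,2418,1935,2902,gamma,THB
SUAVR,all,cost_nonmed_followup_accommodation,383,307,460,gamma,THB
CAVR,all,cost_nonmed_followup_accommodation,368,294,442,gamma,THB
SUAVR,all,cost_nonmed_followup_informal_care,11102,8881,13322,gamma,THB
CAVR,all,cost_nonmed_followup_informal_care,12086,9669,14503,gamma,THB
SUAVR,all,u_30d,0.6419,0.6290,0.6549,beta,utility
CAVR,all,u_30d,0.5790,0.5662,0.5918,beta,utility
SUAVR,all,u_1y,0.8276,0.7828,0.8725,beta,utility
CAVR,all,u_1y,0.8470,0.8069,0.8871,beta,utility
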