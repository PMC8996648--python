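Risk	N06.850
Risk Factors	N06.850.505
Risk Assessment	N06.850.520
Epidemiologic Studies	N05.715.360.775
Case-Control Studies	N05.715.360.775.100
Cohort Studies	N05.715.360.775.175
Follow-Up Studies	N05.715.360.775.175.250
Prospective Studies	N05.715.360.775.175.600
Retrospective Studies	N05.715.360.775.175.700
Prognosis	E01.789
Disease Progression	E01.789.200
Treatment Outcome	E01.789.800
Incidence	E05.318.308.985.525.375
Prevalence	E05.318.308.985.525.700
Mortality	E05.318.308.985.525.580
Fatal Outcome	E05.318.308.985.525.580.300
Survival Rate	E05.318.308.985.525.580.700
Survival Analysis	E05.318.740.996
Disease-Free Survival	E05.318.740.996.295
Kaplan-Meier Estimate	E05.318.740.996.500
Proportional Hazards Models	E05.318.740.996.600
Survival Rate	E05.318.740.996.750
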