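section,concept,year,concept_total,stratum,n_patients,pct_printed
diagnoses_dp1,anemia,2016,5210,ordered,3292,63
diagnoses_dp1,anemia,2017,5690,ordered,3935,69
diagnoses_dp1,anemia,2018,6283,ordered,4299,68
diagnoses_dp1,anemia,2019,6582,ordered,4446,68
diagnoses_dp1,anemia,2020,6609,ordered,4409,67
diagnoses_dp1,anemia,2021,6999,ordered,4660,67
diagnoses_dp1,anemia,2016,5210,billing,4934,95
diagnoses_dp1,anemia,2017,5690,billing,5397,95
diagnoses_dp1,anemia,2018,6283,billing,5973,95
diagnoses_dp1,anemia,2019,6582,billing,6329,96
diagnoses_dp1,anemia,2020,6609,billing,6287,95
diagnoses_dp1,anemia,2021,6999,billing,6713,96
diagnoses_dp1,pericarditis,2016,394,ordered,83,21
diagnoses_dp1,pericarditis,2017,420,ordered,83,20
diagnoses_dp1,pericarditis,2018,464,ordered,91,20
diagnoses_dp1,pericarditis,2019,526,ordered,105,20
diagnoses_dp1,pericarditis,2020,613,ordered,82,13
diagnoses_dp1,pericarditis,2021,651,ordered,125,19
diagnoses_dp1,pericarditis,2016,394,billing,388,99
diagnoses_dp1,pericarditis,2017,420,billing,418,100
diagnoses_dp1,pericarditis,2018,464,billing,458,99
diagnoses_dp1,pericarditis,2019,526,billing,522,99
diagnoses_dp1,pericarditis,2020,613,billing,607,99
diagnoses_dp1,pericarditis,2021,651,billing,643,99
diagnoses_dp1,uremic_bleeding,2016,778,ordered,597,77
diagnoses_dp1,uremic_bleeding,2017,901,ordered,693,77
diagnoses_dp1,uremic_bleeding,2018,858,ordered,664,77
diagnoses_dp1,uremic_bleeding,2019,887,ordered,680,77
diagnoses_dp1,uremic_bleeding,2020,809,ordered,584,72
diagnoses_dp1,uremic_bleeding,2021,828,ordered,594,72
diagnoses_dp1,uremic_bleeding,2016,778,billing,707,91
diagnoses_dp1,uremic_bleeding,2017,901,billing,804,89
diagnoses_dp1,uremic_bleeding,2018,858,billing,787,92
diagnoses_dp1,uremic_bleeding,2019,887,billing,810,91
diagnoses_dp1,uremic_bleeding,2020,809,billing,750,93
diagnoses_dp1,uremic_bleeding,2021,828,billing,762,92
diagnoses_dp1,metabolic_acidosis,2016,987,ordered,37,4
diagnoses_dp1,metabolic_acidosis,2017,1207,ordered,41,3
diagnoses_dp1,metabolic_acidosis,2018,1276,ordered,43,3
diagnoses_dp1,metabolic_acidosis,2019,1596,ordered,41,3
diagnoses_dp1,metabolic_acidosis,2020,1783,ordered,59,3
diagnoses_dp1,metabolic_acidosis,2021,1868,ordered,64,3
diagnoses_dp1,metabolic_acidosis,2016,987,billing,973,99
diagnoses_dp1,metabolic_acidosis,2017,1207,billing,1192,99
diagnoses_dp1,metabolic_acidosis,2018,1276,billing,1260,99
diagnoses_dp1,metabolic_acidosis,2019,1596,billing,1573,99
diagnoses_dp1,metabolic_acidosis,2020,1783,billing,1760,99
diagnoses_dp1,metabolic_acidosis,2021,1868,billing,1845,99
procedures_dp2,kidney_biopsy,2016,145,ordered,91,63
procedures_dp2,kidney_biopsy,2017,156,ordered,101,65
procedures_dp2,kidney_biopsy,2018,140,ordered,73,52
procedures_dp2,kidney_biopsy,2019,171,ordered,92,54
procedures_dp2,kidney_biopsy,2020,157,ordered,79,50
procedures_dp2,kidney_biopsy,2021,199,ordered,110,55
procedures_dp2,kidney_biopsy,2016,145,billing,123,85
procedures_dp2,kidney_biopsy,2017,156,billing,131,84
procedures_dp2,kidney_biopsy,2018,140,billing,121,86
procedures_dp2,kidney_biopsy,2019,171,billing,145,85
procedures_dp2,kidney_biopsy,2020,157,billing,135,86
procedures_dp2,kidney_biopsy,2021,199,billing,172,86
procedures_dp2,dialysis,2016,1249,ordered,1071,86
procedures_dp2,dialysis,2017,1295,ordered,1071,83
procedures_dp2,dialysis,2018,1257,ordered,1063,84
procedures_dp2,dialysis,2019,1409,ordered,1207,86
procedures_dp2,dialysis,2020,1377,ordered,1198,87
procedures_dp2,dialysis,2021,1437,ordered,1224,85
procedures_dp2,dialysis,2016,1249,billing,1241,99
procedures_dp2,dialysis,2017,1295,billing,1290,99
procedures_dp2,dialysis,2018,1257,billing,1251,99
procedures_dp2,dialysis,2019,1409,billing,1396,99
procedures_dp2,dialysis,2020,1377,billing,1370,99
procedures_dp2,dialysis,2021,1437,billing,1422,99
procedures_dp2,pyelography,2016,240,ordered,182,76
procedures_dp2,pyelography,2017,275,ordered,218,79
procedures_dp2,pyelography,2018,283,ordered,230,81
procedures_dp2,pyelography,2019,296,ordered,229,77
procedures_dp2,pyelography,2020,306,ordered,230,75
procedures_dp2,pyelography,2021,405,ordered,322,79
procedures_dp2,pyelography,2016,240,billing,192,80
procedures_dp2,pyelography,2017,275,billing,215,78
procedures_dp2,pyelography,2018,283,billing,202,71
procedures_dp2,pyelography,2019,296,billing,231,78
procedures_dp2,pyelography,2020,306,billing,230,75
procedures_dp2,pyelography,2021,405,billing,302,75
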