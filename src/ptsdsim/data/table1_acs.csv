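attribute,category,proportion
sex,female,0.51452
sex,male,0.48548
age_band,under_20,0.2401
age_band,20_44,0.3315
age_band,45_64,0.2783
age_band,65_plus,0.1501
race_ethnicity,white_nh,0.4040
race_ethnicity,hispanic,0.26976
race_ethnicity,black_nh,0.2690
race_ethnicity,asian_nh,0.0343
race_ethnicity,aian_nh,0.0017
race_ethnicity,other_nh,0.0045
race_ethnicity,two_or_more_nh,0.0167
education,up_to_12th,0.1236
education,high_school,0.2783
education,some_college,0.2177
education,associates,0.0962
education,bachelors,0.1848
education,graduate,0.0994
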