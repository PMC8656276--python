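attribute,category,proportion
sex,female,0.51142
sex,male,0.48858
age_band,under_20,0.2438
age_band,20_44,0.3338
age_band,45_64,0.2774
age_band,65_plus,0.1450
race_ethnicity,white_nh,0.4007
race_ethnicity,hispanic,0.2678
race_ethnicity,black_nh,0.2720
race_ethnicity,asian_nh,0.0345
race_ethnicity,aian_nh,0.0024
race_ethnicity,other_nh,0.0052
race_ethnicity,two_or_more_nh,0.0174
education,up_to_12th,0.1264
education,high_school,0.2809
education,some_college,0.2154
education,associates,0.0964
education,bachelors,0.1844
education,graduate,0.0965
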