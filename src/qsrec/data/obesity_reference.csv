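sex,age_years,median_bmi,obesity_bmi
male,8.5,17.69,23.5
male,9.5,,25.3
female,8.5,17.32,24.7
female,9.5,,25.6
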