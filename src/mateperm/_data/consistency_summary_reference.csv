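trait,observed_delta,expected_delta,expected_sd,p_formatted,effect_pct,ci_lo,ci_hi,icc_pct,pearson_r
residence,0.72,1.23,0.03,<0.001,19.48,18.03,20.9,43.58,0.42
education,0.72,0.87,0.02,<0.001,7.17,6.45,7.88,19.24,0.18
weight,8.82,11.31,0.24,<0.001,16.21,14.04,18.39,33.77,0.31
height,6.3,7.42,0.16,<0.001,11.28,9.53,13.06,24.56,0.22
age_difference,44.05,49.44,1.13,<0.001,10.49,8.41,12.7,13.97,0.14
attractiveness,1.23,1.44,0.03,<0.001,8.28,7.26,9.36,16.49,0.19
masculinity,1.26,1.4,0.03,<0.001,5.51,4.61,6.44,9.71,0.11
eye_color,1.28,1.35,0.03,0.026,2.76,2.17,3.43,4.31,0.05
hair_color,2.54,2.74,0.07,0.001,4.81,3.89,5.77,10.17,0.12
facial_masculinity,1.66,1.46,0.04,1.000,0.07,0.07,0.07,0,-0.05
beardedness,0.67,0.67,0.02,0.575,0.07,0.07,0.07,6.83,0.08
muscularity,1.01,1.03,0.03,0.181,1.27,0.87,1.67,3.43,0.05
bmi,1.25,1.35,0.03,0.002,4.23,3.5,4.99,11.87,0.17
relative_height,1.18,1.5,0.04,<0.001,11.99,10.75,13.3,30.58,0.34
hirsuteness,1.41,1.48,0.04,0.055,2.56,1.93,3.26,10.31,0.12
leg_to_body_ratio,1.21,1.35,0.03,<0.001,5.93,4.98,6.89,13.52,0.12
extraversion,3.12,3.36,0.08,0.002,5.25,4.2,6.41,9.32,0.12
agreeableness,2.94,3.14,0.07,0.003,5.07,4.1,6.11,3.55,0.06
conscientiousness,3.68,3.92,0.09,0.006,4.68,3.62,5.76,5.08,0.09
emotional_stability,3.29,3.57,0.08,0.001,5.84,4.69,7.08,8.1,0.12
openness,2.91,3.21,0.07,<0.001,6.94,5.77,8.16,9.27,0.11
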