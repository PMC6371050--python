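,residence,education,weight,height,age_difference,attractiveness,masculinity,eye_color,hair_color,facial_masculinity,beardedness,muscularity,bmi,relative_height,hirsuteness,leg_to_body_ratio,extraversion,agreeableness,conscientiousness,emotional_stability,openness
residence,19.4,,,,,,,,,,,,,,,,,,,,
education,3.2,7.1,,,,,,,,,,,,,,,,,,,
weight,5.3,1.8,16.1,,,,,,,,,,,,,,,,,,
height,4.0,1.6,5.0,11.2,,,,,,,,,,,,,,,,,
age_difference,3.5,1.5,3.3,2.5,10.3,,,,,,,,,,,,,,,,
attractiveness,2.7,1.4,2.5,2.1,1.7,8.3,,,,,,,,,,,,,,,
masculinity,1.8,0.8,2.2,1.3,1.4,2.1,5.4,,,,,,,,,,,,,,
eye_color,1.1,0.3,0.7,0.6,0.6,0.4,0.2,2.7,,,,,,,,,,,,,
hair_color,1.2,0.7,1.0,0.9,0.3,0.7,0.2,0.6,4.7,,,,,,,,,,,,
facial_masculinity,0.0,0.0,0.0,0.0,0.1,0.0,0.0,0.0,0.0,0.0,,,,,,,,,,,
beardedness,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,,,,,,,,,,
muscularity,0.4,0.1,0.6,0.2,0.1,0.5,0.5,0.1,0.3,0.0,0.0,1.2,,,,,,,,,
bmi,0.6,0.1,1.7,0.3,0.2,0.5,0.6,0.0,0.1,0.0,0.0,0.4,4.2,,,,,,,,
relative_height,4.1,1.4,3.7,4.9,2.8,2.3,1.2,0.6,0.8,0.0,0.0,0.3,0.4,11.9,,,,,,,
hirsuteness,0.9,0.2,1.0,0.3,0.5,0.4,0.4,0.0,0.1,0.0,0.0,0.2,0.4,0.4,2.4,,,,,,
leg_to_body_ratio,2.0,0.7,1.6,2.6,1.3,1.1,0.8,0.1,0.3,0.0,0.0,0.2,0.4,2.4,0.5,5.8,,,,,
extraversion,1.9,0.7,1.7,1.3,0.9,1.2,0.5,0.3,0.5,0.0,0.0,0.1,0.2,1.2,0.4,0.6,5.1,,,,
agreeableness,1.8,0.5,1.6,0.7,0.2,0.9,0.9,0.1,0.2,0.0,0.0,0.2,0.2,0.5,0.4,0.5,1.0,5.0,,,
conscientiousness,1.7,0.7,1.0,0.8,0.7,0.9,0.9,0.1,0.1,0.0,0.0,0.0,0.0,0.6,0.3,0.3,0.9,1.2,4.6,,
emotional_stability,2.2,0.9,2.0,1.4,1.0,1.1,0.8,0.2,0.3,0.0,0.0,0.3,0.3,0.9,0.5,0.5,1.2,2.0,1.3,5.8,
openness,2.5,1.0,1.6,1.2,1.2,1.3,0.8,0.2,0.5,0.0,0.0,0.3,0.3,1.4,0.3,0.4,1.6,1.2,1.0,1.5,6.9
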