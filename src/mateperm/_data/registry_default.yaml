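# Standard 21-trait partner registry: 3 demographic, 13 physical, 5 TIPI
# personality domains. Ordinal image scales are coded in their printed order
# (eye colour gray->black, hair colour light->dark). Age difference is stored
# in months, negative when the woman is older than her partner.
traits:
  - {name: residence, family: demographic, scale_min: 1, scale_max: 4,
     integer_valued: true, description: "size of residence: 1 metropolis .. 4 village"}
  - {name: education, family: demographic, scale_min: 1, scale_max: 4,
     integer_valued: true, description: "1 elementary .. 4 university"}
  - {name: age_difference, family: demographic, scale_min: -300, scale_max: 400,
     integer_valued: true, description: "partner minus respondent age in months; negative = woman older"}
  - {name: weight, family: physical, scale_min: 40, scale_max: 200,
     integer_valued: true, description: "body weight in kg"}
  - {name: height, family: physical, scale_min: 140, scale_max: 220,
     integer_valued: true, description: "body height in cm"}
  - {name: attractiveness, family: physical, scale_min: 1, scale_max: 7,
     integer_valued: true, description: "overall attractiveness, 7-point Likert"}
  - {name: masculinity, family: physical, scale_min: 1, scale_max: 7,
     integer_valued: true, description: "overall masculinity, 7-point Likert"}
  - {name: eye_color, family: physical, scale_min: 1, scale_max: 5,
     integer_valued: true, description: "1 gray, 2 blue, 3 green, 4 brown, 5 black"}
  - {name: hair_color, family: physical, scale_min: 1, scale_max: 9,
     integer_valued: true, description: "9 shades, light blond to black"}
  - {name: facial_masculinity, family: physical, scale_min: 1, scale_max: 5,
     integer_valued: true, description: "image scale, low to high facial masculinity"}
  - {name: beardedness, family: physical, scale_min: 1, scale_max: 4,
     integer_valued: true, description: "image scale, clean shaven to full beard"}
  - {name: muscularity, family: physical, scale_min: 1, scale_max: 6,
     integer_valued: true, description: "image scale, low to high muscularity"}
  - {name: bmi, family: physical, scale_min: 1, scale_max: 6,
     integer_valued: true, description: "image scale, low to high body mass index"}
  - {name: relative_height, family: physical, scale_min: 1, scale_max: 6,
     integer_valued: true, description: "image scale, man-taller to woman-taller pattern"}
  - {name: hirsuteness, family: physical, scale_min: 1, scale_max: 5,
     integer_valued: true, description: "image scale, low to high body hair"}
  - {name: leg_to_body_ratio, family: physical, scale_min: 1, scale_max: 5,
     integer_valued: true, description: "image scale, relatively short to long legs"}
  - {name: extraversion, family: personality, scale_min: 2, scale_max: 14,
     integer_valued: true, description: "TIPI domain score (direct + reverse-keyed item)"}
  - {name: agreeableness, family: personality, scale_min: 2, scale_max: 14,
     integer_valued: true, description: "TIPI domain score"}
  - {name: conscientiousness, family: personality, scale_min: 2, scale_max: 14,
     integer_valued: true, description: "TIPI domain score"}
  - {name: emotional_stability, family: personality, scale_min: 2, scale_max: 14,
     integer_valued: true, description: "TIPI domain score"}
  - {name: openness, family: personality, scale_min: 2, scale_max: 14,
     integer_valued: true, description: "TIPI domain score"}
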