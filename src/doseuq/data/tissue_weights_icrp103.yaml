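# ICRP 103 tissue-weighting factors. Named weights sum with the remainder
# weight to 1.00. The remainder is the arithmetic mean of its member organs;
# prostate (male) / uterus (female) and the gonad target (testes/ovaries)
# are resolved per sample sex.
weights:
  red_marrow: 0.12
  colon: 0.12
  lungs: 0.12
  stomach_wall: 0.12
  breast: 0.12
  gonads: 0.08
  ub_wall: 0.04
  oesophagus: 0.04
  liver: 0.04
  thyroid: 0.04
  endosteum: 0.01
  brain: 0.01
  salivary_glands: 0.01
  skin: 0.01
remainder_weight: 0.12
remainder_members:
  male:
    - adrenals
    - et_airways
    - gb_wall
    - heart_wall
    - kidneys
    - lymph
    - muscle
    - oral_mucosa
    - pancreas
    - prostate
    - si_wall
    - spleen
    - thymus
  female:
    - adrenals
    - et_airways
    - gb_wall
    - heart_wall
    - kidneys
    - lymph
    - muscle
    - oral_mucosa
    - pancreas
    - uterus
    - si_wall
    - spleen
    - thymus
sex_specific:
  gonads:
    male: testes
    female: ovaries
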