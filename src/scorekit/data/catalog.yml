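# Exemplar score catalog: Family Environment Scale (parent report)
# cohesion and conflict subscales, the youth blood-pressure measure, and
# one mental-health exemplar (emotion-regulation attunement subscale).
id_columns: [participant_id, session_id]
missing_codes: []
scores:
  - name: fc_p_fes__cohes_mean
    kernel: mean
    items:
      - fc_p_fes__cohes_001
      - fc_p_fes__cohes_002
      - fc_p_fes__cohes_003
      - fc_p_fes__cohes_004
      - fc_p_fes__cohes_005
      - fc_p_fes__cohes_006
      - fc_p_fes__cohes_007
      - fc_p_fes__cohes_008
      - fc_p_fes__cohes_009
    params:
      max_na: 1
  - name: fc_p_fes__confl_mean
    kernel: mean
    items:
      - fc_p_fes__confl_001
      - fc_p_fes__confl_002
      - fc_p_fes__confl_003
      - fc_p_fes__confl_004
      - fc_p_fes__confl_005
      - fc_p_fes__confl_006
      - fc_p_fes__confl_007
      - fc_p_fes__confl_008
      - fc_p_fes__confl_009
    params:
      max_na: 1
  - name: ph_y_bp__sys_mean
    kernel: mean
    items: [ph_y_bp__sys_001, ph_y_bp__sys_002, ph_y_bp__sys_003]
    params:
      max_na: 1
  - name: ph_y_bp__dia_mean
    kernel: mean
    items: [ph_y_bp__dia_001, ph_y_bp__dia_002, ph_y_bp__dia_003]
    params:
      max_na: 1
  - name: ph_y_bp__hrate_mean
    kernel: mean
    items: [ph_y_bp__hrate_001, ph_y_bp__hrate_002, ph_y_bp__hrate_003]
    params:
      max_na: 1
  - name: mh_p_ders__attun_mean
    kernel: mean
    items:
      - mh_p_ders__attun_001
      - mh_p_ders__attun_002
      - mh_p_ders__attun_003
      - mh_p_ders__attun_004
      - mh_p_ders__attun_005
    params:
      max_na: 1
groups:
  fc_p_fes: [fc_p_fes__cohes_mean, fc_p_fes__confl_mean]
  ph_y_bp: [ph_y_bp__sys_mean, ph_y_bp__dia_mean, ph_y_bp__hrate_mean]
  mh_p_ders: [mh_p_ders__attun_mean]
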