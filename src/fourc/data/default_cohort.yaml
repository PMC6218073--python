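# Default synthetic-cohort configuration: six group-by-sex cells matching
# the reference study's published subject characteristics (mean, SD), at
# the study's cell sizes (total n = 115).  Units: height cm, BMI kg/m2,
# age years, waist cm, true_bf % of body mass.
cells:
  NW/M:
    n: 20
    height_cm: [178.4, 5.8]
    bmi: [23.1, 1.5]
    age: [23.2, 2.9]
    wc_cm: [76.8, 4.2]
    true_bf: [11.0, 4.1]
  NW/F:
    n: 20
    height_cm: [163.6, 6.5]
    bmi: [24.1, 1.7]
    age: [26.4, 8.2]
    wc_cm: [67.2, 4.7]
    true_bf: [20.8, 5.3]
  OW_BMI/M:
    n: 20
    height_cm: [178.6, 9.7]
    bmi: [28.1, 2.8]
    age: [26.5, 9.1]
    wc_cm: [86.3, 6.6]
    true_bf: [17.6, 7.3]
  OW_BMI/F:
    n: 20
    height_cm: [162.6, 7.2]
    bmi: [26.9, 1.6]
    age: [22.0, 2.8]
    wc_cm: [77.0, 5.1]
    true_bf: [33.9, 5.7]
  OW_BMI_WC/M:
    n: 14
    height_cm: [179.1, 8.5]
    bmi: [37.5, 4.8]
    age: [34.6, 10.2]
    wc_cm: [112.0, 10.8]
    true_bf: [34.5, 8.5]
  OW_BMI_WC/F:
    n: 21
    height_cm: [165.4, 5.3]
    bmi: [38.4, 8.0]
    age: [36.9, 13.2]
    wc_cm: [103.8, 14.7]
    true_bf: [44.5, 6.2]

# Physiology: TBW/FFM hydration ratio and BMC/FFM bone fraction, each with
# a between-subject SD.
hydration: 0.732
hydration_sd: 0.01
bone_fraction: 0.05
bone_fraction_sd: 0.004

# Additive device-noise SDs in each instrument's native unit.
adp_bv_sd: 0.3     # ADP body volume, L
dxa_fm_sd: 0.5     # DXA fat mass, kg
dxa_lm_sd: 0.5     # DXA lean mass, kg
dxa_bmc_sd: 0.05   # DXA bone mineral content, kg
tbw_sd: 0.8        # bioimpedance total body water, L

seed: 0
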