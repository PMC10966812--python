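# Dutch base-case scenario: TIL cell therapy versus ipilimumab in
# unresectable stage IIIC-IV melanoma after first/second-line failure.
# Published model inputs (2021 euros); survival curves are log-logistic
# fits to the modelled survival probabilities at months 3-12.
scenario:
  country_label: Netherlands
  currency_label: EUR
  discount_rate_costs: 0.04      # Dutch guideline: 4.0% on costs
  discount_rate_effects: 0.015   # 1.5% on (QA)LYs
  wtp_threshold: 80000           # informal Dutch threshold, euro/QALY
  friction_period_days: 78.9     # provenance of productivity-loss inputs
  # Baseline cohort age is not a published input; 59 y is a documented
  # placeholder (median age of advanced-melanoma trial populations) used
  # only for the age-100 model cutoff.
  baseline_age_years: 59
  cycle_length_years: 0.25

arms:
  - name: TIL-NKI/CCIT
    pfs_curve:
      points_csv: table1_survival_points.csv
      arm: TIL
      endpoint: pfs
      family: loglogistic
    os_curve:
      points_csv: table1_survival_points.csv
      arm: TIL
      endpoint: os
      family: loglogistic
    treatment_costs:
      one_time_items:            # published per-patient treatment bundle
        - [screening, 3822]
        - [til_isolation, 2043]
        - [til_production, 67547]
        - [hospital_admission_and_follow_up, 44528]
      death_cost: 1516           # care in the cycle before death
      follow_up_stop_years: 5    # follow-up assumed cured after 5 years
    societal_costs:
      # direct patient costs + informal care + productivity loss
      first_cycle_amount: 4476   # 227 + 710 + 3539
      per_cycle_amount: 256      # 82 + 99 + 75 per later cycle
      annual_amount: 385         # copay, per year while alive
    pfs_utilities:
      timepoints: [0, 3, 6, 9, 12]
      values: [0.874, 0.879, 0.885, 0.881, 0.887]
      carry_forward: true        # last visit value extends beyond month 12
      pre_death_utility: 0.665
    next_line_mix:
      - {label: ipilimumab_monotherapy, course_cost: 66388, proportion: 0.20, utility: 0.764}
      - {label: braf_mek_inhibitor, course_cost: 101224, proportion: 0.20, utility: 0.844}
      - {label: ipilimumab_nivolumab, course_cost: 72514, proportion: 0.11, utility: 0.695}
      - {label: pembrolizumab, course_cost: 54571, proportion: 0.01, utility: 0.707}
      - {label: no_treatment, course_cost: 0, proportion: 0.43, utility: 0.832}
      # "Other" = 25% temozolomide / 75% ipilimumab+pembrolizumab.
      # The ipilimumab+pembrolizumab component has no published utility;
      # we use the mean of its components, giving
      # 0.25*0.730 + 0.75*(0.764 + 0.707)/2 = 0.734125.
      - {label: other, course_cost: 96448, proportion: 0.05, utility: 0.734125}

  - name: ipilimumab
    pfs_curve:
      points_csv: table1_survival_points.csv
      arm: ipilimumab
      endpoint: pfs
      family: loglogistic
    os_curve:
      points_csv: table1_survival_points.csv
      arm: ipilimumab
      endpoint: os
      family: loglogistic
    treatment_costs:
      one_time_items:
        - [screening, 2507]
        - [ipilimumab_treatment, 75316]
      death_cost: 1516
      follow_up_stop_years: 5
    societal_costs:
      first_cycle_amount: 4665   # 210 + 916 + 3539
      per_cycle_amount: 201      # 27 + 99 + 75
      annual_amount: 385
    pfs_utilities:
      timepoints: [0, 3, 6, 9, 12]
      values: [0.838, 0.840, 0.841, 0.849, 0.828]
      carry_forward: true
      pre_death_utility: 0.665
    next_line_mix:
      - {label: ipilimumab_rechallenge, course_cost: 66388, proportion: 0.02, utility: 0.764}
      - {label: braf_mek_inhibitor, course_cost: 101224, proportion: 0.29, utility: 0.844}
      - {label: pembrolizumab, course_cost: 54571, proportion: 0.10, utility: 0.707}
      # "no further treatment or another trial"; utility of no treatment
      # after ipilimumab.
      - {label: no_treatment_or_other_trial, course_cost: 0, proportion: 0.57, utility: 0.764}
      # "Other" = 50% dacarbazine / 50% temozolomide:
      # 0.5*0.791 + 0.5*0.730 = 0.7605.
      - {label: other, course_cost: 6814, proportion: 0.02, utility: 0.7605}
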