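# Class-conditional population parameters of the 283-patient pheochromocytoma
# surgical cohort used throughout this package as the synthetic-generator default.
#
# class 0 = no intraoperative hemodynamic instability (IHD), n = 209 (73.9%)
# class 1 = IHD, n = 74 (26.1%)
#
# Continuous normal variables carry mean/sd; the skewed urine-metabolite ratio
# (prevma: 24-h urine vanillylmandelic acid / upper normal limit) carries
# median/q1/q3 and is modelled lognormal; binary variables carry the percentage
# of the class with the trait; ordered categorical variables carry per-category
# percentages. Percentages are stored exactly as reported for the source cohort
# and converted to probabilities (renormalized for rounding slack) on load.
n_total: 283
n_cases: 74
features:
  age:
    kind: normal
    encoding: numerical
    by_class:
      0: {mean: 51.9, sd: 12.3}
      1: {mean: 54.0, sd: 13.8}
  sex:                       # percent male
    kind: bernoulli
    by_class:
      0: {percent: 52.6}
      1: {percent: 41.9}
  bmi:                       # kg/m^2
    kind: normal
    encoding: numerical
    support: [0.0, null]
    by_class:
      0: {mean: 24.1, sd: 3.5}
      1: {mean: 21.9, sd: 2.7}
  asa:                       # ASA physical-status score 1-3
    kind: ordinal
    encoding: categorical
    categories: [1, 2, 3]
    by_class:
      0: {percent: [24.9, 65.1, 10.0]}
      1: {percent: [18.9, 71.6, 9.5]}
  dm:                        # diabetes mellitus
    kind: bernoulli
    by_class:
      0: {percent: 29.2}
      1: {percent: 31.1}
  chd:                       # coronary heart disease
    kind: bernoulli
    by_class:
      0: {percent: 31.6}
      1: {percent: 50.0}
  hypertension:              # 0 normal / 1 intermittent / 2 continuous
    kind: ordinal
    encoding: numerical
    categories: [0, 1, 2]
    by_class:
      0: {percent: [39.2, 22.5, 38.3]}
      1: {percent: [40.5, 24.3, 35.1]}
  arrhythmia:
    kind: bernoulli
    by_class:
      0: {percent: 5.7}
      1: {percent: 5.4}
  side:                      # tumor side, percent left
    kind: bernoulli
    by_class:
      0: {percent: 49.3}
      1: {percent: 52.7}
  size:                      # radiographic tumor size, cm
    kind: normal
    encoding: numerical
    support: [0.0, null]
    by_class:
      0: {mean: 5.2, sd: 2.5}
      1: {mean: 6.5, sd: 3.1}
  necrosis:                  # tumor necrosis
    kind: bernoulli
    by_class:
      0: {percent: 33.0}
      1: {percent: 44.6}
  ctvalue:                   # enhanced CT difference, Hounsfield units
    kind: normal
    encoding: numerical
    by_class:
      0: {mean: 43.2, sd: 20.6}
      1: {mean: 45.6, sd: 20.2}
  preablock:                 # preoperative alpha adrenoreceptor antagonists
    kind: bernoulli
    by_class:
      0: {percent: 55.0}
      1: {percent: 56.8}
  precrystal:                # preoperative crystal fluid (reported jointly with colloid)
    kind: bernoulli
    by_class:
      0: {percent: 56.5}
      1: {percent: 39.2}
  precolloid:                # preoperative colloid fluid (reported jointly with crystal)
    kind: bernoulli
    by_class:
      0: {percent: 56.5}
      1: {percent: 39.2}
  preblood:                  # preoperative blood transfusion
    kind: bernoulli
    by_class:
      0: {percent: 25.8}
      1: {percent: 20.3}
  prevma:                    # 24-h urine vanillylmandelic acid / upper normal limit
    kind: lognormal
    encoding: numerical
    support: [0.0, null]
    by_class:
      0: {median: 1.4, q1: 0.9, q3: 2.2}
      1: {median: 1.47, q1: 0.9, q3: 2.7}
  surgeryapproach:           # percent laparoscopic (vs open)
    kind: bernoulli
    by_class:
      0: {percent: 52.2}
      1: {percent: 56.8}
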