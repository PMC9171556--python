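# Twin-pair preset: two continuous standardized symptom scores
# (trait1: obsessive-compulsive symptoms, trait2: alcohol dependence
# symptoms) at age 18.  Components reconstruct the best-fitting AE model of
# the CATSS twin cohort: A shares 36%/46%, E shares 64%/54%, genetic
# correlation 0.31, nonshared environmental correlation 0.10.
name: catss-twin
kind: pairs
measurement: continuous
traits: [ocs, alcohol_dep]
components:
  V_A: [[0.36, 0.1261513377], [0.1261513377, 0.46]]
  V_C: [[0.0, 0.0], [0.0, 0.0]]
  V_E: [[0.64, 0.05878775383], [0.05878775383, 0.54]]
counts: {MZ: 4000, DZ: 5000}
thresholds: null
covariates:
  p_female: 0.601
  birth_year: {low: 1993, high: 2001, reference: 1997}
  # small mean shifts in score SD units: OC symptoms slightly higher and
  # dependence symptoms slightly lower among women in this age band
  effects:
    ocs: {sex: 0.15, birth_year_per_decade: 0.05}
    alcohol_dep: {sex: -0.20, birth_year_per_decade: 0.05}
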