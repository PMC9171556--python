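# Sibling-pair liability preset: bivariate AE structure for two lifetime
# binary diagnoses (trait1: OCD, trait2: any substance misuse) on the
# standardized liability scale.  Component values reconstruct the
# best-fitting AE model of the Swedish register sibling cohort: A shares
# 55%/57%, E shares 45%/43%, genetic correlation 0.28, nonshared
# environmental correlation 0.27 (off-diagonals r * sqrt(v1 * v2)).
name: population-liability
kind: pairs
measurement: binary
traits: [ocd, substance_misuse]
components:
  V_A: [[0.55, 0.156774998], [0.156774998, 0.57]]
  V_C: [[0.0, 0.0], [0.0, 0.0]]
  V_E: [[0.45, 0.1187693142], [0.1187693142, 0.43]]
counts: {FS: 200000, MHS: 20000}
# Liability cutoffs for sex = 0 (male), matching register lifetime
# prevalences: OCD 0.363% men / 0.507% women; misuse 7.75% men / 3.74% women.
thresholds: {ocd: 2.684336237, substance_misuse: 1.422395412}
covariates:
  p_female: 0.489
  birth_year: {low: 1960, high: 1989, reference: 1975}
  # liability mean shifts: sex coefficient applies to females (sex = 1);
  # birth-year trend is per decade, a mild secular registration trend
  effects:
    ocd: {sex: 0.1135658152, birth_year_per_decade: 0.05}
    substance_misuse: {sex: -0.3596951382, birth_year_per_decade: 0.05}
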