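# Methods

This note documents the models the package implements, the calibration of
the synthetic-data presets, the numerical choices that matter, and what the
passing test suite does and does not establish about real data.

## Bivariate ACE model for relative pairs

Two phenotypes per person are decomposed into additive-genetic (A), shared
environmental (C) and nonshared environmental (E) latent components, each
contributing a 2×2 symmetric (co)variance matrix V_A, V_C, V_E.  A pair of
relatives of type *k* shares A with coefficient r_A(k) (MZ 1, DZ/full
siblings ½, maternal half-siblings ¼) and C with coefficient 1, giving the
4×4 implied covariance

    Σ_k = [[P, R_k], [R_k, P]],  P = V_A + V_C + V_E,  R_k = r_A(k) V_A + V_C.

Identification of A against C requires at least two pair types with
different r_A; the designs shipped are MZ+DZ (twin cohort) and FS+MHS
(population sibling cohort).  All pair types are assumed to share their
environment equally, there is no assortative mating, no sex-limitation
(covariates shift means/thresholds only), and pairs are treated as
independent.

**Direct-symmetric parameterization.** The free parameters are the matrix
entries themselves rather than Cholesky factors.  This keeps the null of a
vanishing component on the interior of the parameter space (variance
estimates may legitimately go negative), which is what makes the
likelihood-ratio tests on the model ladder well behaved.  The only hard
constraint is that P be positive definite; the optimizer enforces it with a
large finite penalty rather than a crash, so line searches can back off.

**Continuous likelihood (FIML).** Each pair contributes the log-density of
its *observed* subvector of (m1 t1, m1 t2, m2 t1, m2 t2) under N(μ, Σ_k);
pairs are grouped by missingness pattern and pair type so the computation
is one Cholesky per group.  Means are linear in sex and birth year
((year − reference)/10) per trait.

**Binary (liability-threshold) likelihood.** A lifetime diagnosis is
liability ≥ threshold, with total liability variance fixed to 1 per trait
(the V_E diagonal is derived as 1 − V_A,ii − V_C,ii; the identification
standard for liability-scale models).  Covariates enter as threshold
shifts: sex as a category, birth year binned to decade midpoints, so pairs
aggregate exactly into 16-cell contingency tables per (pair type, sex pair,
decade pair) stratum and the likelihood is Σ counts · log p_cell with cell
probabilities given by rectangles of the implied 4-dimensional liability
normal.  Aggregation loses nothing because covariates are constant within a
stratum; the birth-year coarsening (generation is linear in year, analysis
uses decade midpoints) is a deliberate, practically negligible
approximation.

**Rectangle probabilities.** Cell probabilities use a separation-of-
variables transform of the multivariate normal integral evaluated on a
scrambled-Sobol point set with a fixed internal seed (default 1024–2048
points per rectangle, batched over all cells sharing a correlation
matrix).  The estimator has small *relative* error even for the very rare
concordant cells, and because the point set is fixed the likelihood is a
smooth deterministic function of the parameters — essential for
quasi-Newton optimization and for bit-reproducibility.  The standalone
`mvn_rectangle` doubles the point count until an 8-replicate error estimate
falls below the accuracy target (default 1e-6).

**Optimization.** L-BFGS-B on the unconstrained parameters, forward-
difference gradients with step 1e-6 (large enough that floating-point
noise in a log-likelihood of magnitude ~1e5 does not corrupt the gradient),
relative function tolerance 1e-12, projected-gradient tolerance 5e-4, up to
5 jittered restarts on failure.  Starting values come from moment
estimates: per-pair-type cross-covariances of covariate-residualized
scores (continuous) or tetrachoric correlations with margin-implied
thresholds (binary), solved for V_A/V_C by least squares across pair types.
Standard errors, when requested, come from the inverse observed information
(central finite differences); confidence intervals for derived quantities
(shares, component correlations, covariance shares, implied phenotypic
correlation) use the delta method.  Profile-likelihood intervals were
deliberately not implemented: the delta method is deterministic, cheap and
testable, and the package reports the parameter covariance for anyone who
needs more.

**Model ladder and selection.** ACE-ACE, AE-AE, CE-CE, E-E are fitted and
each reduced model is compared to the full fit by LRT (χ² with df = the
parameter-count difference; dropping one component frees the 3 entries of
its symmetric matrix).  The preferred model is the most parsimonious one
not significantly worse than ACE-ACE at p ≥ 0.05, with AIC breaking ties.
Component correlations are reported as undefined (with a warning) when a
negative estimated diagonal makes them meaningless — an expected
direct-symmetric artifact, flagged rather than clipped.

**Tetrachoric MLE.** The 2×2-table liability correlation maximizes the
multinomial likelihood over ρ with thresholds fixed at the margin-implied
quantiles (optionally user-fixed); SE from the observed information of the
profile.  Perfectly concordant tables clamp to ±(1 − 1e-6) with a warning.

## Phenotypic stage

* **Counting process.** Follow-up runs on the age timescale from entry
  (the 15th birthday or study start, whichever is later) to the first
  recorded outcome or censoring (death, emigration, administrative end).
  A first OCD diagnosis at age d splits follow-up into an unexposed row
  (entry, d] and an exposed row (d, stop]; diagnoses before entry give a
  single exposed row.  Left truncation is handled by risk-set membership,
  not by discarding people.
* **Cox regression** (lifelines; Efron tie handling, the standard choice
  in modern survival practice) adjusts for sex and birth
  year (linear per decade).  Sex-stratified estimates are produced by
  subsetting, not interactions.
* **Kaplan-Meier cumulative incidence** is 1 − S(t) with delayed entry and
  no competing risks; pointwise 95% bands on the log(−log S) scale so the
  interval respects [0, 1].
* **Standardized regression** z-scores outcome and exposure on the
  analysis sample, adjusts for sex and birth year, and uses the
  cluster-sandwich covariance over twin pairs with the small-sample factor
  G/(G−1)·(N−1)/(N−k); with singleton clusters this reduces exactly to
  HC1.

## Synthetic cohorts and preset calibration

The generators emulate the *structure* of a national register linkage and
a twin-cohort questionnaire study; every preset value is calibrated to the
published cohort estimates so that re-estimating the generating parameters
is a meaningful end-to-end check.

* `catss-twin` — MZ/DZ pairs, two continuous standardized scores with AE
  covariance (A shares 0.36/0.46, r_g 0.31, r_e 0.10), sex ~ Bernoulli
  (60.1% female), twin-shared birth years 1993–2001, small sex/secular mean
  shifts (±0.15–0.2 SD for sex; 0.05 SD per decade).
* `population-liability` — FS/MHS pairs, binary lifetime diagnoses by
  thresholding AE liabilities (A shares 0.55/0.57, r_g 0.28, r_e 0.27) at
  sex-specific cutoffs matching register lifetime prevalences (OCD 0.36%
  men / 0.51% women; any misuse 7.7% / 3.7%), birth years 1960–1989 with
  sibling spacing ≤ 5 years and a 0.05/decade liability trend.  The
  three-decade window keeps the likelihood's stratum count small enough
  that a full fit at 220 000 pairs runs in minutes.
* `catss-bocs` — a 12-item never/ever symptom checklist: independent
  probit items with equal loadings 0.7206 and 30% endorsement, a one-off
  Spearman-Brown calibration that puts the sum score's Cronbach α at 0.76.
* `population-registry` — birth years 1975–1995, entry at max(15, age at
  study start 1997), administrative end 2013, death/emigration censoring
  (0.05%/0.2% per year); lifetime-diagnosis flag with log-normal first-
  diagnosis age (median 28.0 years, σ = 0.499 — matching the median
  exactly; the implied IQR 20.0–39.2 is slightly narrower than the
  published 20.3–39.8, which no two-parameter family can match along with
  the median); piecewise-constant baseline hazards on 5-year age bands
  with a young-adult peak.  Alcohol- and drug-related outcomes are pure
  proportional-hazards processes with exposure log-HRs ln 4.51 and
  ln 6.69, sex effects from the register's sex-specific incidence, and a
  0.1/decade cohort trend, with baselines integrating to ~2.6%/~1.6%
  never-exposed cumulative incidence by 32.

Two deliberate departures from strict realism:

* **The diagnosed subgroup is oversampled to 10%** (register: 0.43%).  A
  power calculation at design time showed that a 100 000-person cohort at
  the true prevalence would yield ~7 exposed alcohol events — the Cox HR
  would be unestimable at any useful precision — while 10% preserves
  ~100–150 exposed events and leaves every hazard ratio and baseline at
  its register-calibrated value.
* **The combined alcohol-or-drug outcome is a separate descriptive
  process**, not the union of the two: its hazard carries a constant
  lifetime-diagnosis group multiplier ψ = ln 0.77 / ln 0.95 ≈ 5.10 from
  entry, calibrated so the two cumulative-incidence tracks reach exactly
  23% (diagnosed) and 5% (general population) by age 32.  The published
  figure contrasts *lifetime* groups and is therefore confounded by shared
  liability; a pure time-varying-exposure model that reproduces the causal
  hazard ratios cannot also reproduce that descriptive gap, so the preset
  encodes the two targets through two mechanisms and documents which is
  which.  Event clocks start at entry, matching what a register beginning
  in 1997 can observe and making delayed-entry estimators exactly
  consistent with the generating hazards.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: the same person appearing in both a full- and a
half-sibling pair (pairs are disjoint; the fitter's independence assumption
is exact here but approximate in a real register); treatment-seeking
selection and primary-care undercapture; calendar-period effects and
competing risks; item-level local dependence in scales; reverse causation
between the traits.

## Problem sizes and known limitations

The test suite and acceptance script run at deliberately scaled-down sizes
chosen as a design point: 4 000 + 5 000 twin pairs (the cohort's own
scale), 200 000 + 20 000 sibling pairs (~8% of the register's sibling
subcohort), registries of 100 000–200 000 persons.  One consequence is
worth stating plainly: with a 0.43%-prevalence trait, 200 000 sibling pairs
contain only ~17 trait-1-concordant pairs, so the liability-scale a² for
that trait is weakly identified (SE ≈ 0.10 versus ≈ 0.025 at the register's
1.66 million pairs) and its point estimate can sit 20–30% from the
generating value on a given seed even though the estimator is correct; the
genetic correlation, which borrows strength from the cross-trait cells, is
much more stable.  Recovery tests therefore judge that share against the
fit's own estimated SE.

Other limitations: no sex-limitation or gene-environment interaction
models; no polychoric (>2 category) support and no liability integrals
beyond dimension 4; no ascertainment correction; implied phenotypic
correlations computed from *rounded* published shares differ from the
published phenotypic correlations in the second decimal (0.2755 vs 0.27;
0.1849 vs 0.19) — an arithmetic property of the rounded inputs, reported
as computed.
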