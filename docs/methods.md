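# Methods

## Four-group IHC classification

Each case carries one resolved intensity score (0–3) and positive-proportion
percentage per compartment; any observer-reconciliation process happens
upstream of this package. The binary rule is defined on intensity only
(tumor positive at ≥ 2, stroma positive at ≥ 1 by default), because the
published cutoffs are intensity cutoffs; proportions are carried through and
reported but do not enter the rule. Cutoffs can be re-derived from data by
ROC analysis with the recurrence indicator as the positive class: candidate
thresholds are the distinct observed scores under "positive iff score ≥ t",
the selected threshold maximizes Youden's J, and ties are broken toward the
smaller (more sensitive) threshold. The direction convention and the
tie-break are package choices; the underlying rule ("optimal cutoff by ROC")
does not fix either.

## DEG screen

Expression enters as TPM and every effect is defined on log₂(TPM+1). The
screen contrasts Group 1 against the pooled Groups 0/2/3; per-pair contrasts
are deliberately not implemented. The per-gene test is Welch's unequal-
variance t-test — a package choice, since the defining criterion only fixes
the p-value threshold — and the `test` argument of `screen_degs` accepts any
callable returning `(statistic, p)` so a rank-based test can be swapped in.
A gene is a DEG when |Δ| ≥ 1 and raw *p* < 0.05; BH-FDR over all tested
genes is attached for volcano/enrichment use (an option to restrict the BH
family is unnecessary: callers can subset the matrix before screening).
Degenerate genes with zero variance in both groups get *p* = 1 when the
means agree and *p* = 0 otherwise (the difference is then observed without
noise). Volcano rows report −log₁₀(FDR), capped at 300 for FDR = 0 with a
`capped` flag.

## ssGSEA and the snoRNA module

The single-sample enrichment score ranks a sample's genes by increasing
expression (average ranks on ties; tied ranks are walked in input gene
order, a documented determinism choice), walks them in decreasing-rank
order, and accumulates P_in − P_out, where P_in weights set members by
rank^α (α = 0.25, the convention of the ssGSEA methodology; configurable)
and P_out counts non-members uniformly. The score depends only on ranks, so
it is invariant to any strictly increasing transform of the sample's values
— log₂(TPM+1) is used for concreteness. No cross-sample min–max
normalization is applied by default. Signature membership is matched by gene
symbol, case-sensitively, because the signatures are defined as symbol
lists; an ambiguous (duplicated) symbol match is an error rather than a
silent sum. The snoRNA module score is the arithmetic mean of raw TPM (not
log) over the Group-1-enriched snoRNA set. Continuous scores are z-scored
(sample SD) before multivariable modeling.

## snoRNA annotation and ORA

The annotation table is a plain TSV input — the bundled table covers the
Group-1-enriched snoRNA set with snoDB 2.0-style attributes, with paralog
family rows (SNORA21/21B, SNORD111/111B) expanded to one row per member
symbol — so there is no network or database dependence and provenance is
versioned with the repository. Box class implies modification chemistry
(H/ACA → Ψ, C/D → 2′-O-Me); a violation raises a warning, not an error,
since the table is user-replaceable. Host genes are deduplicated
order-stably before enrichment. Over-representation uses the upper-tail
hypergeometric p (P(X ≥ k)), sets intersected with the user-supplied
background first, BH across sets. GO/KEGG term collections themselves are
inputs, not bundled.

## Survival and association statistics

Kaplan–Meier, the k-sample log-rank test, Cox regression and the C-index are
delegated to lifelines; chi-square, Fisher, Mann–Whitney, Spearman and the
hypergeometric test to scipy; BH to statsmodels. Conventions fixed here:

* **Cox**: Efron tie handling (a `ties="breslow"` flag routes through
  statsmodels' PHReg); Wald CIs and p-values, matching per-covariate
  presentation; monotone partial likelihood (separation) is detected from
  the optimizer's diagnostics and reported as `converged=False` with a flag
  rather than raised; collinear covariates raise.
* **Schoenfeld check**: scaled residuals correlated with transformed event
  time; identity transform by default, KM transform by flag. A numerical
  property worth knowing: with heavy-tailed raw times the identity-transform
  variant is conservative (≈1% rejections at nominal 5% in a 200-replicate
  exponential-time simulation at n=300), while the KM transform is
  calibrated; the test suite asserts exactly this.
* **Chi-square**: Pearson without continuity correction by default — the
  variant that reproduces the published 2×4 TPM-by-group statistic
  (χ² = 0.254, df = 3, *p* = 0.968); Yates available by flag. Because the
  test actually used per row of published 2×2 tables is often unstated, the
  association report gives Pearson, Yates and Fisher p-values side by side
  plus the minimum expected count (<5 suggesting Fisher).
* **Fisher**: two-sided by the minimum-likelihood convention (all tables
  with the observed margins whose probability ≤ the observed table's),
  which differs from doubling the one-sided tail.
* **Mann–Whitney**: exact null enumeration when n_x + n_y ≤ 20 without
  ties; tie-corrected normal approximation otherwise; U equal to its null
  mean reports p = 1 exactly.
* **C-index**: Harrell's, pairs comparable iff the shorter follow-up is an
  event, tied risks count ½.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, with
defaults matching the study conditions:

| parameter | default | why |
|---|---|---|
| n_cases | 111 | cohort size |
| group_probs | 45/111, 35/111, 19/111, 12/111 | observed group split |
| effect_log2 | ±1.5 per marker | a strong DEG effect; the screen's own bar is \|Δ\| ≥ 1 |
| noise_sd_log2 | 1.0 | realistic between-patient spread of bulk log₂ TPM |
| baseline_log2_range | (0.5, 8) | spans low-to-high expressed genes |
| group1_log_hr | ln 4.877 | the Group-1 univariable recurrence hazard ratio |
| baseline_hazard | 0.002 /month | with the censoring below, yields ~20% events, matching 22/111 recurrences |
| censor_time_max | 120 months | ~10-year administrative follow-up, censoring uniform on (0, 120] |
| covariate_freqs | per-group Bernoulli rates from the observed 35-vs-76 counts | group-conditional covariate mix |

Marker genes reuse the published signature symbols (11 snoRNAs up, 3
protein-coding up, 11 protein-coding down) so symbol-matched scoring works
on simulated data unchanged; SDC1 itself is included as a neutral gene.
Expression noise is Gaussian on log₂(TPM+1) and back-transformed
(2^y − 1, clipped at 0) — the scale on which the effects are defined. IHC
intensities are drawn uniformly inside the score range implied by the case's
group, so classification recovers the generating group for 100% of cases;
positive proportions are uniform 10–100%. Survival times are exponential
with the Group-1 proportional hazard. One seed feeds deterministic
per-component sub-streams (groups, IHC, covariates, expression, survival),
so e.g. enlarging the gene panel never changes the clinical draws.

What the generator does **not** model: tumor purity, spatial structure,
sequencing-depth/count noise (the analysis consumes TPM only), covariate
correlations beyond group membership, non-exponential baseline hazards, and
informative censoring. Passing recovery tests therefore demonstrates
correctness of the analysis machinery under the assumed model, not
robustness to real-data artifacts. The within-group variance and censoring
distribution are conventions chosen here, not published facts.

## Problem sizes used in validation

Simulation-based checks use 200 replicates: Cox CI coverage of the planted
hazard ratio at n = 500 under light censoring; Group-1-vs-others log-rank
power at n = 111 (under the study's event rate the 4-group log-rank's power
is ≈91%, right at the 90% bar, while the Group-1 contrast — the comparison
of scientific interest — has ≈96% power and is what the acceptance test
asserts); DEG calibration/power at the study's 35-vs-76 split with 24 null
genes and one planted 1.5-shift gene per replicate; Schoenfeld calibration
at n = 300. Oracle-equivalence tests (Fisher enumeration, Mann–Whitney
enumeration, concordance pair counting, partial-likelihood grid search) run
at n ≤ 30 where brute force is exact. The large-n hazard-ratio recovery in
the acceptance script uses n = 2000.

## Known limitations

* The published per-covariate Cox hazard ratios cannot be reproduced
  without individual-level follow-up data, which are not published; they are
  used only as planted truths for simulation recovery.
* Published per-row association p-values for some 2×2 tables match none of
  the three standard variants computed from the printed counts; the package
  reports all three rather than guessing.
* ssGSEA scores are not min–max normalized across samples; comparisons
  across differently sized gene panels should use ranks or z-scores.
* The ORA stage tests over-representation only (no competitive or
  permutation-based gene-set testing).
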