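# Methods

## The generative model

The simulator produces one child per family under the standard additive
quantitative-genetics decomposition. For individual *i* of sex *s*,

    height_i = μ_s + σ_s · ( √h²·g_i + √c²·C_f(i) + √(1−h²−c²)·e_i )

with `g` a standardized additive genetic value, `C` a family-level
standard-normal environment shared by mother, father and child, and `e`
unique environment; all three components are mutually independent.
Genetic values come from `L` unlinked biallelic loci: effect-allele
frequencies `f_j ~ U(freq_range)`, founder dosages `Binomial(2, f_j)`
(Hardy-Weinberg), normal per-locus effects on a randomly chosen causal
subset, rescaled so the theoretical genetic variance `Σ β²·2f(1−f)`
equals exactly 1 — hence `Var(g) = 1` and the within-sex genetic
variance share equals h² by construction. Children receive one allele
per locus from each parent, sampled uniformly (Mendelian transmission;
loci independent, no linkage).

Mates are paired by Gaussian-copula rank matching on the phenotype
component that exists before a family does (genetic + unique
environment): a latent bivariate-normal sample with correlation ρ_am is
drawn, mothers sorted by phenotype take the ranks of the first
coordinate and fathers those of the second. The shared environment is
added after pairing, so the realized spousal phenotypic correlation is
ρ_am·(1−c²) + c² — with the defaults (ρ_am = 0) spousal correlation
equals c², the minimal structure by which parents share the child's
environment.

Under the defaults (random mating, c² = 0) the package's oracle checks
are the textbook closed forms, exact up to Monte-Carlo error:
parent-child within-sex correlation h²/2; single-parent R² = h⁴/4;
mid-parental R² = h⁴·(σ_F+σ_M)²/(4(σ_F²+σ_M²)) — h⁴/2 at equal SDs,
0.3193 at the default 6.2/6.8 cm SDs; perfect-score R² = h²; and the
child-on-midparent slope h² *on the sex-standardized scale* (the
cm-scale within-sex slope differs by σ-ratios when the sexes' SDs
differ, which is why the slope check standardizes first).

### Defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| n_families | 5000 | trios per cohort |
| n_loci / n_causal | 1000 / all | unlinked biallelic loci; `n_causal` thins the causal set |
| allele_freq_range | (0.05, 0.95) | common variants only |
| h² | 0.8 | narrow-sense heritability of adult height |
| c² | 0.0 | shared family-environment variance fraction |
| ρ_am | 0.0 | target spousal phenotypic correlation |
| sex means / SDs | 162.6/175.8 cm, 6.2/6.8 cm | adult female/male height moments of a large UK reference cohort |
| growth_ages | 8.0–17.0 by 0.5 | half-year childhood measurement grid |
| growth_noise_sd | 1.5 cm | self-report measurement noise (no published magnitude exists; a plausible self-measurement error) |

Childhood height at age *a* is `adult_height × frac(sex, a)` plus
measurement noise, where `frac` is a packaged monotone growth-completion
fraction per sex (piecewise-linear in age, girls maturing ~2 years ahead
of boys, `frac(sex, 17) ≥ 0.99`); weight applies a simple age-indexed
BMI reference to the noiseless height. This deliberately omits
pubertal-timing heterogeneity: every child follows the same completion
curve, so age-specific predictions are cleaner than in real cohorts and
the Khamis-Roche R²-by-age curves rise monotonically. Passing tests
therefore certify the arithmetic and the statistical machinery, not the
real-world difficulty of pubertal prediction.

## Score construction (desk scale)

`marginal_gwas` fits per-variant OLS of height on dosage adjusting for
sex via Frisch-Waugh residualization; constant-dosage variants are
flagged (β = NaN, p = 1) and excluded downstream. The default pipeline
splits the training children in two and combines the halves by
fixed-effect inverse-variance weighting — `β = Σ(βᵢ/SEᵢ²)/Σ(1/SEᵢ²)`,
`SE = (Σ1/SEᵢ²)^(−1/2)` — after harmonizing alleles (sign flip on
swapped orientation), exercising the meta-analytic path on every run.

Clumping is greedy in ascending p (ties broken by variant id for
deterministic builds): an index variant removes unselected neighbours
within a variant-count window whose squared dosage correlation exceeds
`r2_threshold`; each p-threshold then keeps its sublist with the
meta-analytic weights. The LASSO arm minimizes
`(1/2n)‖y − a − Zc − Xb‖² + λ‖b‖₁` by cyclic coordinate descent with
soft-thresholding, intercept and sex unpenalized, predictors
standardized internally and coefficients reported on the dosage scale;
convergence is max standardized-coefficient change < 10⁻⁶, with a hard
failure (naming the λ) at 10⁴ sweeps. The λ grid is data-driven:
8 log-spaced points from λ_max = max|X̃'ỹ|/n down to λ_max/100. At λ = 0
the solver reproduces the normal-equation solution to 10⁻⁴, and on
orthonormal designs the closed-form soft-threshold — both frozen as
oracle tests. Model selection maximizes adjusted R² (with sex) on the
held-out selection split, ties going to the smaller model, then to the
first name.

## Scoring and calibration

Scoring files use the PGS-Catalog tab-separated dialect ('#' metadata,
header row, rsID- or chr:pos-keyed records). Harmonization against a
panel keeps exact allele matches, keeps swapped-orientation variants
with the dosage complemented (d → 2−d) at scoring time, and discards
absent or allele-inconsistent variants; `kept + flipped + discarded`
always equals the model size, and a global allele-label flip of the
panel leaves every score invariant (both property-tested). Sporadic
missing dosages are imputed with 2·EAF of the panel by default
(per-variant mean selectable; the two coincide in expectation under
Hardy-Weinberg sampling). Strand-ambiguous A/T and C/G variants are
kept when ids match — simulated data have no strand problem — with a
`--drop-palindromic` flag for real data.

Raw scores are standardized within a reference group (default: all
scored samples; the choice of reference population is a config knob
since conventions differ) and calibrated to centimeters by regressing
height on standardized score plus sex on the training split — the
minimal reading of "genetically predicted height", chosen because no
published conversion rule exists. The calibration refuses any overlap
between its training ids and a declared evaluation set.

## Predictors

* `mph`: (mother + father)/2 − 6.5 cm (girls) / + 6.5 cm (boys); the
  boy-girl difference is exactly 13 cm.
* `adapted_mph`: 0.75·parental mean + 37.85 cm (girls),
  0.78·parental mean + 45.99 cm (boys) — published Swedish regression
  constants, used as printed rather than refitted (refitting is a
  one-liner with `fit_combined_predictor` if a user wants the
  population-specific variant).
* `mother`, `father`, `prs+mph`, `prs+mother`, `prs+father`: least
  squares on the training split; sex is included unless a component
  already encodes it (standard MPH does). Exactly collinear component
  sets (e.g. MPH with both single parents) raise rather than silently
  dropping a column.
* `kr_mph`, `kr_prs`: Khamis-Roche predictions
  `intercept + c_h·height + c_w·weight + c_m·genetic_component` at
  coefficients keyed by (sex, age rounded to the nearest half-year,
  exact ties rounding up). The genetic component is a pure plug-in:
  mid-parental height and a calibrated score height give identical
  predictions wherever their values coincide. The original published
  coefficients are not reproduced here; the package ships a clearly
  labelled synthetic table fitted to this simulator plus
  `fit_kr_table()` to derive one from any training split, and the TSV
  is editable for users transcribing the published values.

## Evaluation

Short stature is labelled within sex from the evaluation cohort's own
moments — height < mean − 2·SD (≈ the 2.28% tail under normality), with
an empirical-quantile mode that agrees with the SD rule on >99% of a
large Gaussian cohort. Discrimination metrics use risk = −predicted
height. AUROC is the tie-aware Mann-Whitney estimator (equal to the
exhaustive pairwise probability; property-tested on all small inputs).
AUPRC is average precision with a conservative tie order (within a tied
score, positives ranked after negatives), avoiding interpolation
optimism; its random-score baseline is the case prevalence. The odds
ratio per SD decrease is exp(−β̂) from a maximum-likelihood logistic fit
(optionally with sex — reported both ways since conventions vary) with
a Wald 95% CI; complete separation raises with advice to use the
ridge-penalized fallback, which the report assembler applies
automatically at very small case counts. Nested linear predictors are
compared with the Gaussian likelihood-ratio statistic `n·ln(RSS₀/RSS₁)`
against χ² with the added *rank* as degrees of freedom (duplicated
columns add nothing). Confidence intervals for R²/RMSE/AUROC/AUPRC are
percentile bootstrap (B = 2000 by default in the CLI, 500 in the
pipeline config), case-resampled, stratified by label for
classification metrics, and fully seeded; the method is deliberately
uniform and assumption-light rather than metric-specific (no DeLong
variance).

## Orchestration and reproducibility

`run_experiment` executes simulate → construct (or load an external
scoring file — exactly one source must be active) → score → predict →
evaluate, writing every artifact as TSV/JSON plus a manifest with the
config hash, per-stage wall times, the seed registry and SHA-256
digests of every output; re-running an unchanged config reproduces the
digests bit-for-bit. Children split 80 : 1.5 : 18.5 into
train/selection/test; all reported metrics come from the test split.
The age-resolved Khamis-Roche comparison drops any half-year age with
fewer than 50 test children of either sex.

## Problem sizes and numerical notes

The closed-form checks run at 50 000 trios (±0.02 bands ≈ 4–6
Monte-Carlo SDs), the shared-environment contrast at 20 000 trios and
400 loci (the closed forms do not depend on locus count), the
construction recovery at 1000 loci / 50 causal / h² = 0.5 with a
4000/800/1600 split, and bootstrap-coverage simulation at 200 datasets
× 600 resamples (n = 400, 20% cases) — sizes chosen so each check is
decisively powered while the whole suite stays interactive. Dosages are
stored as int8 with −1 for missing and widened blockwise for linear
algebra. Degenerate inputs fail loudly: zero reference-SD
standardization, single-class labels, empty candidate or harmonized
sets, rank-deficient designs, non-nested LRT models.

## Known limitations

No linkage disequilibrium beyond optionally duplicated columns, no
X-chromosome dosage, no genotyping error or imputation uncertainty, no
pubertal-timing variation, no population structure (hence no principal
components in the association model), and no non-European
allele-frequency panels. The shipped Khamis-Roche table is synthetic.
With all causal loci genotyped and unlinked, the constructed score
approaches its h² ceiling far more easily than any real score does;
absolute metric values on the simulator are therefore optimistic, while
the orderings and the closed-form relationships are the meaningful
outputs.
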