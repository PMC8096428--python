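# Methods

## Models

### Linear age-trend tests

The three age groups (6/12/18 months) are coded a = (−0.5, 0, 0.5), so the
age coefficient is an effect per year and the trend test is a 1-df
likelihood-ratio comparison of nested models. A linear trend is more
powerful than a 2-df categorical age test and still detects monotone
nonlinear change; with only three time points nothing richer is
identifiable.

**Counts.** Each gene's counts follow a negative-binomial log-link GLM with
offset `log(size factor)` and fixed effects intercept, age, sex and
sequencing batch. The gene-wise dispersion α (Var = μ + αμ²) is estimated
by maximizing the profile likelihood over log α (bounded in [e⁻¹⁸, e³])
under the full model, then held fixed while the full and reduced models are
refit; LRT = 2(ℓ_full − ℓ_reduced) against χ²₁. The coded-unit coefficient
is divided by ln 2 so estimates read as log₂ fold change per year. No
empirical-Bayes dispersion shrinkage is applied: with ~190 samples the
gene-wise ML estimate is stable, and keeping the estimator simple makes the
test's sampling behavior transparent (see Calibration below). Non-convergent
or all-zero genes are returned flagged, excluded from the multiple-testing
family, and counted in the run log.

**Protein.** Abundances are transformed to rank-normal scores per protein
and modeled with fixed intercept, age and sex plus crossed random
intercepts for the isobaric labeling tag (~16 levels) and the cohort
generation (~5 levels). Writing V(γ) = I + Σₖ γₖ ZₖZₖᵀ with γₖ the variance
ratios, the fixed effects and residual variance are profiled out in closed
form by GLS, and the profiled ML log-likelihood is maximized directly over
γ ≥ 0 (L-BFGS-B from two starts, explicit check of the γ = 0 boundary;
boundary fits are valid and flagged). Every per-evaluation quantity is
reduced via the Woodbury identity to operations on q×q cross-products
(q = total random-effect levels ≈ 21), so a gene costs milliseconds. ML
(not REML) is used throughout because the LRT compares models with
different fixed effects. A dense-V GLS evaluation — the brute-force
oracle — is kept in the test suite and agrees to 10⁻⁴.

Both tests expose the focal term: substituting sex for age (age becomes a
covariate) reuses the identical machinery.

### Multiple testing

Each result table carries Holm-adjusted p-values (family-wise, used at
α = 0.05) and Benjamini–Hochberg q-values (used at the deliberately liberal
q < 0.1 for the cross-platform comparison, where losing doubly-measured
genes is costlier than a few false inclusions). Ties are ordered by
(p, feature id) for bit-reproducibility.

### Concordance

Effect sizes from the two platforms live in incomparable units, so each
gene is summarized by z = estimate/SE per platform. Genes with q < 0.1 on
both platforms are classified by sign quadrant (A both up, B mRNA↓/
protein↑, C mRNA↑/protein↓, D both down); everything else is NS. Percent
concordant is (A+D)/N·100 over all shared genes N. When several protein
isoforms map to one gene, the isoform with the smallest raw p is kept (the
choice is logged); a z of exactly 0 on a doubly-significant gene is a
contradiction and raises.

### Mediation scan

Per gene, ordinary least squares of rank-normal protein on
`Age + Sex + Generation` and on `mRNA + Age + Sex + Generation` (Gaussian
LRT on the focal term; tag is omitted, matching the simpler fixed-effects
model this analysis specifies). `delta = −log₁₀p_base − (−log₁₀p_adj)`.
The scan is summarized by the median delta, the fraction exceeding δ₀
(default 0.5, i.e. a ~3-fold p-value drop — the method itself prescribes
only the identity-line comparison, so δ₀ is a reporting convenience, not a
verdict threshold), and the major-axis (first principal component) slope of
the (base, adj) cloud.

Interpretation caveat worth stating: conditioning on an mRNA that itself
trends with age removes *shared* age signal whether or not the protein
effect is causally mediated. On synthetic cohorts, concordant-class genes
(independent age effects of the same sign on both platforms) show positive
deltas and discordant-class genes negative ones (suppression); the
cohort-level median stays near zero because the classes and the null genes
balance. The scan's contrast is therefore a population-level statement —
compare the age scan to the sex scan on the same genes — not a per-gene
causal test.

### Urinary phenotypes

Analytes are adjusted for urinary creatinine before analysis — by default
the residual of log(analyte) on log(creatinine); a log-ratio option exists.
Below-detection readings are floored (half the detection threshold) before
the log. The phenotype mediation test reports the age p-value from
`Phenotype ~ Age + Sex` and `Phenotype ~ Protein + Age + Sex` side by side,
plus the sex-adjusted partial correlation of phenotype and protein; no
dichotomous verdict is forced.

### Structure

PCA operates on feature-centered rank-normal data (no rescaling — the
scores are already on a common scale); variance fractions come from squared
singular values, component signs are fixed by the largest-|loading|
feature, and each component's scores are tested against age (linear) and
sex (factor) by an F-test. Surrogate proportion variables are the first PC
of a cell type's standardized marker submatrix in upper-quartile-normalized
bulk data, extracted without regressing out any covariate ("raw"
extraction) so that downstream age-trend tests on the SPVs are untouched by
the extraction; markers are genes whose reference mean in their top type
exceeds the runner-up type by ≥ 2-fold (ratio rule; this package's own
definition), capped at 50 per type. The over-representation test is the
exact hypergeometric upper tail on user-supplied two-column (gene, term)
annotations; no ontology parsing or term propagation.

## Synthetic cohort generator

The generator emulates a 188-animal cross-sectional design: per-(age, sex)
cell counts (30/33, 31/31, 34/29), a 2-level RNA batch, a ~16-level MS tag,
5 generations, one measurement per animal. Genes belong to labelled classes
(concordant up/down, the two discordant classes, mRNA-mediated, null) whose
true slopes are recorded in a truth table. The wiring encodes the central
contrast: protein age effects in the non-mediated classes are *direct*
(never routed through mRNA), sex effects are always transcriptionally
driven (protein sex = λ × mRNA sex component), and mediated genes receive
their whole protein age signal as λ × the mRNA age component, so
`protein_age_slope = λ · mrna_age_slope` holds exactly in the truth table.
mRNA and protein share a latent per-gene, per-sample biological term (the
protein couples to the latent log-mean, not the sampled count, so counting
noise attenuates without destroying within-age correlation).

Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| `mrna_age_effect` | 0.5 | log-mean slope per year (natural log) |
| `protein_age_effect` | 0.5 | direct protein slope per year, residual-SD units — the planned detectable trend of the design |
| `mrna_sex_effect`, `sex_effect_fraction` | 0.8, 0.8 | strong, pervasive sex differences (most genes sex-significant in kidney at this scale) |
| `mediation_lambda` | 0.7 | mRNA→protein transfer |
| `bio_sd` | 0.3 | shared latent biological variation (log scale) |
| `protein_noise_sd` | 0.5 | residual protein noise; reflects high-precision multiplexed proteomics, and is the largest value at which the generator's own invariants (mediated genes distinguishable, median delta > 1) hold |
| `dispersion_range` | (0.05, 0.3) | NB dispersion, typical bulk RNA-seq |
| `libsize_log_sd` | 0.3 | log-normal library size, makes size-factor estimation non-trivial |
| `batch_sd`, `tag_sd`, `generation_sd` | 0.3, 0.3, 0.2 | technical/structural effect SDs |

Default class counts total 6,500 genes (the scale of a
both-platforms-measured kidney gene set); tests and the acceptance suite
run the generator at a few hundred to two thousand genes, sizes chosen so
each property is measured with adequate replication while the full suite
stays in minutes.

What the generator does **not** emulate: genetic (founder-haplotype)
effects, peptide-level measurement structure, isoform multiplicity,
mean-dependent dispersion trends, and any real correlation structure among
genes beyond the shared sample-level factors. Passing tests therefore
demonstrate the estimators' statistical correctness under the assumed
generative families, not robustness to everything real data contains.

The bulk-mixture fixture for deconvolution multiplies profile×proportion
signal by gene-level log-normal noise and a per-sample library-size factor;
markers are kept to a few percent of the gene universe, as in real
transcriptomes — if markers dominate the universe, upper-quartile
normalization itself tracks composition and corrupts the SPVs.

## Calibration and numerical choices

* On exact NB null simulations (64/group, 2000 genes) the count trend test
  rejects at 0.046–0.056 at nominal 0.05; the mixed-model test at ~0.056 on
  Gaussian nulls with tag/generation effects present. With the generator's
  additional log-normal biological layer the NB test becomes mildly liberal
  (~0.067) — a model mis-specification effect (log-normal vs gamma mixing),
  listed here as a known limitation.
* Dispersion profile: bounded scalar optimization, xatol 10⁻³ on log α.
* LMM optimizer: L-BFGS-B, ftol 10⁻¹², two starts plus explicit γ = 0
  evaluation; variance ratios at the boundary are flagged `vc_boundary`.
* OLS LRTs guard the degenerate perfect-fit case (response inside the
  design span): the focal p is reported as 1 when the reduced model already
  fits to rounding error. Partial correlations return (0, 1) when a
  residual vanishes numerically.
* Rank-normal scores use mid-ranks for ties and quantile offset 0.5
  (configurable to 0.375/Blom); the offset convention is not pinned by the
  literature the transform comes from.
* Tables are written with `%.17g` floats and read back with exactly-rounding
  parsing, so write→read round-trips are bit-exact and equal-seed runs are
  byte-identical.
* The variance-stabilizing step is a shifted log₂ of depth-normalized
  counts (pseudocount 1). It is used only ahead of rank-normalization and
  PCA-style analyses, where any monotone variance-flattening transform is
  interchangeable; the rank-normal step downstream erases all but the
  ordering anyway.

## Known limitations

* Protein trend estimates are reported on the rank-normal scale; no
  back-transform to abundance units is attempted (none is well defined),
  so cross-platform comparisons go through z-scores only.
* The mediation scan is a significance-drop comparison, not a causal
  mediation estimator (no mediated-effect estimands or bootstrap CIs).
* The NB test's nominal level degrades under overdispersion families other
  than gamma-Poisson (see Calibration).
* Deconvolution SPVs are relative, standardized summaries — they order
  samples by a cell type's abundance but carry no absolute proportion.
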