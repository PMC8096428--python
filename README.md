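# duotrend

Joint mRNA–protein age-trend, concordance and mediation analysis for
cross-sectional cohorts measured on two molecular platforms.

## The problem

Bulk transcriptomics is often used as a proxy for the proteome, but in
aging tissue the two layers can move independently: a gene's protein can
rise with age while its mRNA falls, and vice versa. Disentangling which
protein changes are transcriptionally driven requires measuring both layers
in the same animals and asking, gene by gene, whether the age effect on
protein survives adjustment for the corresponding mRNA. `duotrend`
implements that analysis end to end for a three-age-group cross-sectional
design (e.g. genetically diverse mice at 6, 12 and 18 months), together
with a synthetic cohort generator so every stage is testable without any
data download.

## The statistics

Age enters every model as a coded linear term, a = (−0.5, 0, 0.5) for the
three groups, so one coded unit spans a year and a 1-df likelihood-ratio
test of the age coefficient is a linear trend test.

* **mRNA counts** — negative-binomial log-link GLM per gene,
  `log E[y] = β₀ + βₐ·a + sex + batch + log(size factor)`, gene-wise
  dispersion estimated by maximum likelihood under the full model and shared
  by the nested fits; size factors are the median-of-ratios estimator.
  Estimates are reported as log₂ fold change per year.
* **protein abundances** — rank-based inverse-normal scores per protein,
  then a linear mixed model with fixed sex and crossed random intercepts for
  the mass-spec labeling tag and the cohort generation; full and reduced
  models are fit by ML with the variance ratios optimized directly on the
  profiled log-likelihood.
* **multiple testing** — Holm (family-wise, "adjusted p") and
  Benjamini–Hochberg ("FDR q") per result table.
* **concordance** — per-platform trend z-scores (estimate/SE); genes with
  q < 0.1 on both platforms fall into sign quadrants A (both up),
  B (mRNA↓/protein↑), C (mRNA↑/protein↓), D (both down).
* **mediation scan** — per gene, the focal term's −log₁₀ p on protein from
  `Protein ~ Age + Sex + Generation` versus the same model plus mRNA;
  `delta = base − adjusted` measures how much of the effect the transcript
  absorbs. The same machinery tests sex as the focal term and a urinary
  phenotype against a candidate mediator protein.
* **structure** — PCA variance partitioning with per-component age/sex
  association tests; marker-based cell-type deconvolution via surrogate
  proportion variables (first PC of each type's standardized markers);
  hypergeometric over-representation tests for user-supplied gene sets.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/03_mediation_scan.py` simulates a 188-sample cohort in
which protein aging is mRNA-independent but sex differences are
transcriptionally driven, scans both focal terms, and prints:

```
focal=age_coded: median delta +0.75, major-axis slope 1.07, 54% of genes drop by >0.5
focal=      sex: median delta +3.78, major-axis slope 0.45, 88% of genes drop by >0.5
truly mediated genes only: median age delta +1.21
```

The sex scan's large median delta (the −log₁₀ p drops by almost four
decades once mRNA is in the model) says sex effects on protein are carried
by the transcript; the genes simulated with genuinely mRNA-mediated age
effects show the same signature (+1.21), while the cohort-wide age scan
stays near the identity line. `examples/01_simulate_and_test_trends.py`
prints per-platform significant-gene counts and the recovery of simulated
slopes (r ≈ 0.98); `examples/04_pca_and_deconvolution.py` shows sex
dominating mRNA PC1 and a planted immune-cell-like fraction detected with a
tiny trend q-value.

A thin CLI mirrors the stages: `duotrend simulate|trends|concordance|
mediate|structure|all --config cfg.txt --seed 1 --out results/`.

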