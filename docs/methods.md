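# Methods

## Response: the per-sample point-mutation rate

The response of the regression is the per-sample count of somatic
single-nucleotide variants divided by 20 000, the nominal number of human
protein-coding genes. Only MAF records with `Variant_Type == SNP` are
counted; insertions, deletions and multi-nucleotide types (DNP/TNP map to
"other") are excluded. Whether silent or non-coding SNVs should also be
excluded is not a settled convention; by default no
`Variant_Classification` filter is applied, because exome-derived MAFs are
already coding-dominated, and an `exclude_classifications` option exists
for sensitivity analysis. The denominator is likewise configurable but the
default of 20 000 is the definition of the rate and should not normally be
changed.

## Expression transform

All regression and correlation work is done on t = log₂(x + 1) of the
non-negative expression values. Raw expression is heavy-tailed and would
let a handful of highly expressed genes dominate least squares; the +1
keeps zeros finite. Since the input units (counts/FPKM/TPM) are not fixed
by the method, the package standardises on this one transformed scale and
applies it identically at training and scoring time.

## Model and selection

The model is linear, Y = XB + ε, with an intercept (mutation rates have a
positive baseline even at low enzyme expression). Model size is controlled
by a subset-size penalty: supports are compared by

  RSS + λ·m,  m = number of predictors.

A penalty written as a scalar subtracted inside the residual would be
absorbed by the intercept and have no effect, so the size-penalised
criterion above is the only well-posed reading, and within a fixed support
the fit is plain OLS.

Selection runs in stages, per random split:

1. **Lasso pre-screen** over all EC-annotated enzyme genes (columns
   standardised; objective (1/2n)‖y − Xb‖² + α‖b‖₁). By default α is
   chosen by BIC along the LARS path, which is deliberately sparse;
   cross-validated and fixed-α modes are available
   (`TrainConfig.lasso_selection`, `lasso_alpha`).
2. **EC-class restriction** to transferases (EC 2.-) and hydrolases
   (EC 3.-) by default (`ec_classes`). Genes with several EC numbers
   belong to every listed class and sub-subclass.
3. **Backward elimination**: iterated OLS refits dropping *all* genes with
   coefficient p > 0.05 each round (`drop_all=False` switches to
   one-at-a-time removal, p-ties broken by gene symbol) until every
   retained gene is significant. The final-model contract — max retained
   p ≤ 0.05 whenever the model is non-empty — is asserted by tests.
4. **Support pruning under RSS + λ·m**: greedy backward removal of the
   gene whose removal most improves the criterion, refitting each time.
   This step exists because the pre-screen plus p-filter alone is biased:
   genes picked by the Lasso out of a large pool carry optimistically
   small p-values (classical post-selection bias), and at a residual
   signal-to-noise ratio of 10 it leaves one or two spurious genes per
   cohort. The default weight is the extended-BIC calibration
   λ = σ̂²(log n + 2 log P), with P the size of the screened candidate
   pool and σ̂² the residual variance of the current fit; the classical
   σ̂² log n weight (available as `bic_lambda`, or any fixed
   `subset_lambda`) under-penalises precisely when P is comparable to n.
   On the package's synthetic cohorts this choice takes planted-support
   recovery from F1 ≈ 0.9 to exact recovery without affecting the
   noiseless or null cases. After pruning, the p ≤ 0.05 contract is
   re-asserted by a final elimination pass.

Training repeats over `n_restarts` (default 20) random 2/3–1/3
train/test splits and returns the model with the highest held-out Pearson
correlation; restart index, held-out r and R² are recorded in the model.
An optional `max_subclasses` cap (rank sub-subclasses by contribution,
keep the top k, refit) is off by default: the number of sub-subclasses a
model uses is treated as an emergent property, not a constraint.

The **contribution of an EC sub-subclass** (first three EC fields, e.g.
3.4.21) is the product of the final p-values of the selected genes in that
sub-subclass, computed in log space; an underflowed p of exactly 0 makes
the product 0.

## Scoring and stage summaries

A sample's score is intercept + Σ B_g·t_g — the model applied to the same
transform as training. Controls are scored with the tumor-trained model;
there is no re-fitting. Scores are reported raw, on the mutation-rate
scale (SNVs per gene), not rescaled. Stage labels like "Stage IIIA" are
collapsed to 1–4 by their leading Roman numeral (unparseable labels are
dropped with a warning). The stage summary reports per-group n, mean,
median and quartiles, and two qualitative flags evaluated on **means**
(chosen over medians for determinism; medians are still reported):
tumor mean > control mean, and strict increase of stage means — plus a
relaxed flag tolerating a single out-of-order adjacent pair.

## Validation statistics

* **Pearson r** with the two-sided p from t = r√((n−2)/(1−r²)) on n−2
  degrees of freedom; zero-variance input is an error, never a NaN.
* **Panel validation** reports per-gene r, r² and p against the score for
  the fatty-acid, mucin and glutathione panels (both r and r² because
  users of such panels quote either); "best" is the maximum r, ties
  broken lexicographically.
* **Differential expression** is a Welch two-sample t-test per gene on
  transformed expression, flagged at p < 0.05. The t-test is the stated
  significance procedure of the analysis; no count-model DE machinery is
  wrapped.
* **Over-representation** of a gene list in GMT sets uses the one-sided
  hypergeometric tail P(X ≥ k) within a user-given universe, with
  Benjamini–Hochberg adjustment across sets and a flag at adjusted
  p < 0.05. This reproduces the procedure class of web enrichment tools
  with a user-supplied database rather than a bundled one.

## The synthetic cohort generator

The generator is first-class, tested code; it emulates exactly the
structure the analysis assumes:

* transformed expression t ~ Normal(μ_g, σ_g) per gene (μ_g ∈ [2, 6],
  σ_g ∈ [0.8, 1.6]), clipped at 0, so natural-scale expression
  2^t − 1 is non-negative and log-normal-like;
* a planted support of `n_causal` genes (default 6 of 200) with positive
  coefficients drawn from `coef_range` (default 5·10⁻⁴–2·10⁻³, giving
  cohorts of roughly 100–900 SNVs per genome, the magnitude seen across
  real tumor cohorts) and EC labels from `ec_subclasses` (default 2.7.1
  and 3.4.21); other genes get decoy subclasses, ~10% carry two EC
  numbers;
* latent stress = Σ B_g·t_g; SNV counts are round(20000·(latent + ε)),
  ε ~ Normal(0, `noise_sd`), clipped at 0, plus an indel admixture
  (default 0.2 records per SNP record) that exercises the SNP-only
  counting rule. The default `noise_sd` of 4·10⁻⁴ is about a tenth of the
  typical latent sd under the default geometry, i.e. a signal-to-noise
  ratio near 10 — a strong but not degenerate planted signal;
* stage structure is implanted **through expression**: each tumor of
  stage s has `stage_effect`·s added to its latent stress by shifting the
  causal genes' transformed expression (the shift divided across the
  support by the coefficient total), controls get no shift. A predictor
  that only sees expression can therefore recover the gradient — a pure
  response offset could not be, and would only masquerade as noise;
* validation panels (FASN/ACAT1/ACAT2/MCAT, the 20 mucins,
  GCLC/GCLM/GSS) are extra rows whose transformed expression is linear in
  the standardised latent stress at correlation `validation_rho`
  (default 0.8).

All randomness flows from one seed through named substreams, and two calls
with the same config are byte-identical, including the written files.

What the generator does **not** emulate: negative-binomial count noise,
gene–gene correlation among non-causal genes, batch effects, copy-number
signal, tumor purity. Passing tests on these cohorts therefore demonstrate
correctness of the estimation machinery under the model's own assumptions,
not performance on real tumor data.

## Numerical choices and degenerate inputs

* Count quantization: rounding 20000·latent to integer counts injects a
  rate error of up to 1/40 000 per sample. The noiseless-identifiability
  checks therefore regress on the generator's exact latent response, where
  recovery is analytically forced; through the count path the same setup
  is correct only to quantization accuracy.
* Rank-deficient designs raise an error naming the dependent columns
  (found by pivoted QR) rather than silently pseudo-inverting.
* Zero-variance genes are excluded from the design (they carry no
  information and break standardisation) and from co-expression output.
* p-value ties during one-at-a-time elimination, best-gene ties in panels
  and equal co-expression strengths are all broken by gene symbol so runs
  are reproducible to the byte.
* Duplicate gene rows in expression input are collapsed by mean with a
  warning; duplicate sample columns are an error.

## Problem sizes used in tests

The default test suite and the acceptance script run on cohorts of 120–800
samples and 60–200 enzyme genes with 2–3 split restarts — sizes at which
every statistical property under test (oracle equivalence, support
recovery, null calibration, stage monotonicity, determinism) is already
stable, and the full suite completes in well under a minute of CPU.

## Known limitations

* The EC-class restriction and the p-product contribution statistic are
  taken as given by the method being implemented, not re-derived; the
  p-product is a descriptive ranking, not a calibrated p-value for the
  subclass.
* The "best trained model" criterion (maximum held-out Pearson r over
  restarts) selects optimistically; the reported held-out r of the winner
  is slightly biased upward.
* Welch's t-test on log-transformed expression is a reasonable default for
  the tumor/control comparison but is not a substitute for count-aware DE
  models when library sizes vary wildly.
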